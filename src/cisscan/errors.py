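"""Exception hierarchy.

Every user-facing error contract has a distinct, named class so callers can
catch precisely the failure they expect.
"""


class CisscanError(Exception):
    """Base class for all cisscan errors."""


# --- FASTA input -----------------------------------------------------------

class FastaError(CisscanError):
    pass


class EmptyFastaError(FastaError):
    """FASTA file contained no records."""


class DuplicateSequenceIdError(FastaError):
    """Two FASTA records share the same id."""


class InvalidSequenceError(FastaError):
    """Sequence contains a character outside the IUPAC nucleotide alphabet."""


# --- annotation input ------------------------------------------------------

class AnnotationError(CisscanError):
    pass


class GeneCountError(AnnotationError):
    """Zero or more than one gene feature in the annotation."""


class ExonLayoutError(AnnotationError):
    """Exon interval outside the gene span, unsorted or overlapping."""


class StrandMissingError(AnnotationError):
    """Gene feature carries no usable strand."""


# --- window / coordinates --------------------------------------------------

class WindowError(CisscanError):
    pass


class WindowOutsideSequenceError(WindowError):
    """Requested analysis window does not intersect the available sequence."""


class HitOutsideWindowError(CisscanError):
    """A site hit lies outside the locus analysis window."""


# --- motifs / scanning -----------------------------------------------------

class MotifError(CisscanError):
    pass


class InvalidMotifError(MotifError):
    """Motif too short or containing non-IUPAC characters."""


class MotifTooLongError(MotifError):
    """Motif longer than the window being scanned."""


class ScanParameterError(CisscanError):
    """Out-of-range scan parameter (e.g. min_consecutive)."""


# --- enrichment ------------------------------------------------------------

class EnrichmentParameterError(CisscanError):
    """Inconsistent observed/trial counts or probabilities."""


# --- qPCR ------------------------------------------------------------------

class QPCRError(CisscanError):
    pass


class RegionMismatchError(QPCRError):
    """Measurements for different regions combined."""


class EmptyReplicatesError(QPCRError):
    """A measurement with no Ct replicates."""


# --- synthetic data --------------------------------------------------------

class PlantingError(CisscanError):
    pass


class OverlappingPlantingError(PlantingError):
    """Two planted sites overlap, or a planting falls out of bounds."""


# --- pipeline --------------------------------------------------------------

class ConfigError(CisscanError):
    """Invalid or incomplete pipeline configuration."""


class PipelineError(CisscanError):
    """A pipeline stage failed; message carries the stage name."""
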
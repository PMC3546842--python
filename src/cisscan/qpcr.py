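"""ChIP-qPCR percent-input and fold enrichment over an IgG control.

The percent-input method: the input aliquot is a known fraction f of the
chromatin, so its measured Ct is first adjusted by log_E(1/f) cycles (E =
amplification efficiency per cycle, 2.0 at 100%); the immunoprecipitate then
recovers

    percent_input = 100 * E ** (adjusted_input_Ct - mean_IP_Ct)

Fold enrichment of a specific antibody over the non-specific IgG control is
the ratio of their percent-input values; the input dilution cancels.
Technical duplicates are averaged on the Ct scale within an experiment;
means and standard deviations across independent experiments are computed on
the linear (percent / fold) scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from statistics import mean, stdev

import pandas as pd

from .errors import EmptyReplicatesError, QPCRError, RegionMismatchError

ANTIBODIES = ("specific", "control_igg", "input")

QPCR_COLUMNS = ["region", "antibody", "experiment", "replicate", "ct",
                "input_fraction"]


@dataclass(frozen=True)
class QPCRMeasurement:
    """Ct replicates for one region / one antibody / one experiment."""

    region_name: str
    antibody: str
    ct_replicates: tuple[float, ...]
    input_fraction: float = 0.01
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if self.antibody not in ANTIBODIES:
            raise QPCRError(
                f"antibody must be one of {ANTIBODIES}, got {self.antibody!r}"
            )
        if not self.ct_replicates:
            raise EmptyReplicatesError(
                f"no Ct replicates for {self.region_name}/{self.antibody}"
            )
        if any(ct <= 0 for ct in self.ct_replicates):
            raise QPCRError("all Ct values must be positive")
        if not (0 < self.input_fraction <= 1):
            raise QPCRError("input_fraction must be in (0, 1]")
        if not (1 < self.efficiency <= 2):
            raise QPCRError("efficiency must be in (1, 2]")

    @property
    def mean_ct(self) -> float:
        return mean(self.ct_replicates)

    @property
    def sd_ct(self) -> float:
        if len(self.ct_replicates) < 2:
            return 0.0
        return stdev(self.ct_replicates)


@dataclass(frozen=True)
class PercentInput:
    """Percent of input chromatin recovered, with replicate SD propagated."""

    value: float
    sd: float

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class EnrichmentStat:
    """Summarised ChIP enrichment at one region."""

    region_name: str
    percent_input_specific: float
    percent_input_igg: float
    fold_over_igg: float  # NaN when the IgG percent is 0
    sd: float  # between-experiment SD of fold; NaN for a single experiment
    n_experiments: int = 1


def _log_eff(x: float, efficiency: float) -> float:
    return math.log(x) / math.log(efficiency)


def adjusted_input_ct(input_measurement: QPCRMeasurement) -> float:
    """Input Ct corrected for the input dilution (f of the chromatin):
    mean input Ct - log_E(1/f)."""
    if input_measurement.antibody != "input":
        raise QPCRError("adjusted_input_ct expects an input measurement")
    return input_measurement.mean_ct - _log_eff(
        1.0 / input_measurement.input_fraction, input_measurement.efficiency
    )


def percent_input(
    ip: QPCRMeasurement, input_measurement: QPCRMeasurement
) -> PercentInput:
    """Percent of input chromatin recovered by the immunoprecipitate."""
    if ip.region_name != input_measurement.region_name:
        raise RegionMismatchError(
            f"IP region {ip.region_name!r} != input region "
            f"{input_measurement.region_name!r}"
        )
    if input_measurement.antibody != "input":
        raise QPCRError("second argument must be the input measurement")
    eff = input_measurement.efficiency
    adj = adjusted_input_ct(input_measurement)
    value = 100.0 * eff ** (adj - ip.mean_ct)
    # delta-method propagation of the replicate SDs of both mean Cts
    var = 0.0
    for m in (ip, input_measurement):
        n = len(m.ct_replicates)
        var += (m.sd_ct ** 2) / n
    sd = value * math.log(eff) * math.sqrt(var)
    return PercentInput(value=value, sd=sd)


def fold_over_control(
    specific_percent: float | PercentInput,
    control_percent: float | PercentInput,
) -> float:
    """Ratio of percent-input values (specific antibody over IgG)."""
    spec = float(specific_percent)
    ctrl = float(control_percent)
    if ctrl <= 0:
        warnings.warn(
            "control (IgG) percent input is zero or negative; "
            "fold enrichment reported as NA",
            stacklevel=2,
        )
        return math.nan
    return spec / ctrl


def summarize_experiments(
    per_experiment: list[EnrichmentStat],
) -> EnrichmentStat:
    """Average independent experiments.

    Percent-input values are averaged on the linear scale; the summary fold is
    the ratio of mean percents, and ``sd`` is the between-experiment standard
    deviation of the per-experiment folds (NaN for a single experiment).
    """
    if not per_experiment:
        raise QPCRError("no experiments to summarise")
    regions = {s.region_name for s in per_experiment}
    if len(regions) != 1:
        raise RegionMismatchError(
            f"cannot summarise across regions {sorted(regions)}"
        )
    mean_spec = mean(s.percent_input_specific for s in per_experiment)
    mean_igg = mean(s.percent_input_igg for s in per_experiment)
    folds = [s.fold_over_igg for s in per_experiment]
    if len(per_experiment) > 1:
        sd = stdev(folds) if all(math.isfinite(f) for f in folds) else math.nan
    else:
        sd = math.nan
    fold = mean_spec / mean_igg if mean_igg > 0 else math.nan
    return EnrichmentStat(
        region_name=per_experiment[0].region_name,
        percent_input_specific=mean_spec,
        percent_input_igg=mean_igg,
        fold_over_igg=fold,
        sd=sd,
        n_experiments=len(per_experiment),
    )


# --- Ct tables -------------------------------------------------------------

def read_qpcr_csv(path) -> pd.DataFrame:
    """Read a Ct table CSV with columns region, antibody, experiment,
    replicate, ct, input_fraction."""
    df = pd.read_csv(path)
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise QPCRError(f"Ct table missing columns {missing}")
    bad = set(df["antibody"]) - set(ANTIBODIES)
    if bad:
        raise QPCRError(f"unknown antibody labels {sorted(bad)}")
    return df


def analyze_qpcr_table(
    table: pd.DataFrame, efficiency: float = 2.0
) -> pd.DataFrame:
    """Per-region enrichment summary from a long-format Ct table.

    For each region and experiment, technical duplicates are averaged on the
    Ct scale, percent input is computed for the specific antibody and the IgG
    control against that experiment's input, and the per-experiment folds are
    then summarised across experiments.
    """
    rows = []
    for region in table["region"].drop_duplicates():
        sub = table[table["region"] == region]
        per_exp: list[EnrichmentStat] = []
        for exp in sorted(sub["experiment"].drop_duplicates()):
            esub = sub[sub["experiment"] == exp]
            measurements = {}
            for antibody in ANTIBODIES:
                asub = esub[esub["antibody"] == antibody]
                if asub.empty:
                    raise QPCRError(
                        f"region {region!r} experiment {exp!r} lacks "
                        f"{antibody!r} measurements"
                    )
                measurements[antibody] = QPCRMeasurement(
                    region_name=str(region),
                    antibody=antibody,
                    ct_replicates=tuple(float(x) for x in asub["ct"]),
                    input_fraction=float(asub["input_fraction"].iloc[0]),
                    efficiency=efficiency,
                )
            spec = percent_input(measurements["specific"], measurements["input"])
            igg = percent_input(measurements["control_igg"], measurements["input"])
            per_exp.append(
                EnrichmentStat(
                    region_name=str(region),
                    percent_input_specific=spec.value,
                    percent_input_igg=igg.value,
                    fold_over_igg=fold_over_control(spec, igg),
                    sd=math.nan,
                )
            )
        summary = summarize_experiments(per_exp)
        rows.append(
            {
                "region": summary.region_name,
                "percent_input_specific": summary.percent_input_specific,
                "percent_input_igg": summary.percent_input_igg,
                "fold_over_igg": summary.fold_over_igg,
                "sd_fold": summary.sd,
                "n_experiments": summary.n_experiments,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region", "percent_input_specific", "percent_input_igg",
            "fold_over_igg", "sd_fold", "n_experiments",
        ],
    )
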
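"""Reference-sample microsphere blood-flow computation.

Absolute flow of a tissue sample follows from the ratio of its microsphere
signal to the signal of a blood sample withdrawn at a known constant rate:

    absolute_flow = tissue_signal / reference_signal * withdrawal_rate
    per_gram_flow = absolute_flow / tissue_weight

Signals may be sphere counts or spectrofluorometric intensities in arbitrary
units; the ratio is identical either way, but tissue and reference must be
measured on the same color channel.  Inputs are assumed spillover-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import defaults
from .errors import InvalidInputError, UndefinedFlowError

__all__ = [
    "TissueSample",
    "ReferenceSample",
    "FlowEstimate",
    "MicrosphereAssay",
    "flow_per_sample",
    "assay_flows",
    "region_flow",
    "qc_sample_counts",
    "read_tissue_csv",
    "read_reference_csv",
    "flows_to_frame",
]


@dataclass(frozen=True)
class TissueSample:
    sample_id: str
    region: str
    weight: float          # g
    signal: float          # count or fluorescence a.u.
    color: str = ""

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise InvalidInputError(f"sample {self.sample_id}: weight must be > 0")
        if self.signal < 0:
            raise InvalidInputError(f"sample {self.sample_id}: signal must be >= 0")


@dataclass(frozen=True)
class ReferenceSample:
    withdrawal_rate: float  # mL/min
    signal: float
    color: str = ""

    def __post_init__(self) -> None:
        if self.withdrawal_rate <= 0:
            raise InvalidInputError("withdrawal_rate must be > 0")
        if self.signal < 0:
            raise InvalidInputError("reference signal must be >= 0")


@dataclass(frozen=True)
class FlowEstimate:
    sample_id: str
    region: str
    weight: float
    absolute_flow: float   # mL/min
    per_gram_flow: float   # mL/min/g
    color: str = ""


@dataclass(frozen=True)
class MicrosphereAssay:
    """One measurement's worth of tissue samples plus its reference sample."""

    tissue: tuple[TissueSample, ...]
    reference: ReferenceSample


def flow_per_sample(tissue: TissueSample, ref: ReferenceSample) -> FlowEstimate:
    """Reference-sample flow for one tissue sample."""
    if tissue.color != ref.color:
        raise InvalidInputError(
            f"sample {tissue.sample_id}: color {tissue.color!r} does not match "
            f"reference color {ref.color!r}"
        )
    if ref.signal == 0:
        raise UndefinedFlowError(
            f"sample {tissue.sample_id}: reference signal is zero"
        )
    absolute = tissue.signal / ref.signal * ref.withdrawal_rate
    return FlowEstimate(
        sample_id=tissue.sample_id,
        region=tissue.region,
        weight=tissue.weight,
        absolute_flow=absolute,
        per_gram_flow=absolute / tissue.weight,
        color=tissue.color,
    )


def assay_flows(
    assay: MicrosphereAssay,
    min_signal: float | None = None,
    exclude_flagged: bool = True,
) -> list[FlowEstimate]:
    """Flows for every tissue sample in an assay, with optional QC exclusion.

    ``min_signal=None`` applies no QC filter; pass a threshold (see
    :func:`qc_sample_counts`) to drop low-count samples.
    """
    samples = assay.tissue
    if min_signal is not None and exclude_flagged:
        flagged = qc_sample_counts(assay, min_signal)
        samples = tuple(s for s in samples if s.sample_id not in flagged)
    return [flow_per_sample(s, assay.reference) for s in samples]


def qc_sample_counts(
    assay: MicrosphereAssay, min_signal: float = defaults.MIN_SIGNAL
) -> set[str]:
    """IDs of tissue samples whose signal falls below the precision floor.

    The default floor corresponds to the conventional ~400-sphere minimum for
    acceptable counting statistics; it is a documented default, never applied
    silently by :func:`flow_per_sample`.
    """
    return {s.sample_id for s in assay.tissue if s.signal < min_signal}


def region_flow(estimates: list[FlowEstimate]) -> pd.DataFrame:
    """Per-region summary of per-gram flows.

    Weight-weighted mean (sum of absolute flows over total weight), the
    unweighted mean for comparison, the across-sample sd, and n.
    """
    if not estimates:
        raise InvalidInputError("no flow estimates to summarize")
    df = flows_to_frame(estimates)
    rows = []
    for region, grp in df.groupby("region", sort=True):
        w = grp["weight_g"].to_numpy()
        per_gram = grp["per_gram_flow_ml_min_g"].to_numpy()
        rows.append(
            {
                "region": region,
                "n_samples": len(grp),
                "weighted_mean_flow": float(np.sum(per_gram * w) / np.sum(w)),
                "unweighted_mean_flow": float(per_gram.mean()),
                "sd_flow": float(per_gram.std(ddof=1)) if len(grp) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def flows_to_frame(estimates: list[FlowEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in estimates],
            "region": [e.region for e in estimates],
            "weight_g": [e.weight for e in estimates],
            "color": [e.color for e in estimates],
            "absolute_flow_ml_min": [e.absolute_flow for e in estimates],
            "per_gram_flow_ml_min_g": [e.per_gram_flow for e in estimates],
        }
    )


# ----------------------------------------------------------------------- IO


def read_tissue_csv(path: str | Path) -> list[TissueSample]:
    """Columns: sample_id, region, weight_g, color, signal."""
    df = pd.read_csv(path)
    required = {"sample_id", "region", "weight_g", "color", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    return [
        TissueSample(
            sample_id=str(row.sample_id),
            region=str(row.region),
            weight=float(row.weight_g),
            signal=float(row.signal),
            color=str(row.color),
        )
        for row in df.itertuples()
    ]


def read_reference_csv(path: str | Path) -> ReferenceSample:
    """Columns: color, signal, withdrawal_rate_ml_min (single row)."""
    df = pd.read_csv(path)
    required = {"color", "signal", "withdrawal_rate_ml_min"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    if len(df) != 1:
        raise InvalidInputError(f"{path}: expected exactly one reference row")
    row = df.iloc[0]
    return ReferenceSample(
        withdrawal_rate=float(row["withdrawal_rate_ml_min"]),
        signal=float(row["signal"]),
        color=str(row["color"]),
    )
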
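"""Longitudinal barcode tracking from dead cells shed into culture medium.

Barcoded cells that die during selection release their DNA into the
growth medium; sequencing the pelleted dead cells at regular medium
changes yields a non-destructive time series of clonal composition.
This module assembles per-barcode frequency trajectories over medium
timepoints, re-applies the endpoint growth-rate classification using
the last medium sample as the endpoint frequency, and quantifies how
closely the final medium composition matches the harvested population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from clonetrace.classify import F0Mode, classify_barcodes, compute_frequencies
from clonetrace.extract import CountMatrix


@dataclass
class TrajectorySet:
    """Per-barcode frequency trajectories for one replicate arm.

    ``traj`` is barcodes x timepoints (columns ordered as ``times``, in
    weeks); each column is normalized over the retained barcodes.
    ``endpoint_freq`` holds the harvested-sample frequencies on the same
    barcode index; ``labels`` (optional) carries endpoint phenotype calls.
    """

    times: list[float]
    traj: pd.DataFrame
    endpoint_freq: pd.Series
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.traj.columns) != list(self.times):
            raise ValueError("trajectory columns must equal `times`")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if not self.traj.index.equals(self.endpoint_freq.index):
            raise ValueError("trajectory and endpoint barcode indices differ")

    @property
    def last_medium(self) -> pd.Series:
        return self.traj[self.times[-1]]


def build_trajectories(
    medium_cms: list[CountMatrix],
    endpoint_cm: CountMatrix,
    replicate: str,
    medium_weeks: list[float],
    calls: pd.DataFrame | None = None,
) -> TrajectorySet:
    """Assemble frequency trajectories over medium timepoints.

    ``medium_cms`` holds one count matrix per timepoint (each containing a
    medium sample column for this replicate's arm); ``endpoint_cm`` is the
    filtered harvested-endpoint matrix whose barcode set defines the
    trajectory ID space.  Barcodes missing from a medium sample get
    frequency 0; each timepoint is renormalized over retained barcodes
    because the absolute amount of shed DNA varies between changes.
    """
    if len(medium_cms) < 2:
        raise ValueError("need >= 2 medium timepoints")
    if len(medium_cms) != len(medium_weeks):
        raise ValueError("one week number per medium count matrix")
    barcodes = endpoint_cm.counts.index
    cols: dict[float, np.ndarray] = {}
    for week, cm in zip(medium_weeks, medium_cms):
        medium_samples = cm.samples_in_arm("medium-timepoint-")
        if len(medium_samples) != 1:
            raise ValueError(
                f"expected one medium sample per timepoint matrix, got {medium_samples}"
            )
        if not barcodes.isin(cm.counts.index).all():
            raise ValueError("inconsistent barcode library between samples")
        counts = cm.counts[medium_samples[0]].reindex(barcodes, fill_value=0)
        total = counts.sum()
        cols[week] = (counts / total).to_numpy() if total > 0 else np.zeros(len(barcodes))
    traj = pd.DataFrame(cols, index=barcodes)

    endpoint_counts = endpoint_cm.counts[replicate]
    endpoint_freq = endpoint_counts / endpoint_counts.sum()

    labels = None
    if calls is not None:
        rep_calls = calls[calls["replicate"] == replicate]
        labels = rep_calls.set_index("barcode_id")["label"].reindex(barcodes)
    return TrajectorySet(
        times=list(medium_weeks), traj=traj, endpoint_freq=endpoint_freq, labels=labels
    )


def temporal_growth_classification(
    ts_by_replicate: dict[str, TrajectorySet],
    dmso_counts: pd.Series,
    T: float,
    f0_mode: F0Mode = "per_barcode_dmso",
) -> pd.DataFrame:
    """Endpoint-style phenotype calls using the last medium timepoint as f_R.

    Applies the growth-rate sign rule per replicate with the DMSO control
    as baseline; sharing of positive growth across the replicate medium
    series separates pre-existing from de novo exactly as for harvested
    endpoints.  A barcode counts as detected in a replicate's series when
    its last-medium frequency is nonzero.
    """
    if len(ts_by_replicate) < 2:
        raise ValueError("temporal classification needs >= 2 replicate series")
    reps = sorted(ts_by_replicate)
    barcodes = ts_by_replicate[reps[0]].traj.index
    for rep in reps[1:]:
        if not ts_by_replicate[rep].traj.index.equals(barcodes):
            raise ValueError("replicate trajectory sets use different barcode spaces")

    dmso_total = dmso_counts.reindex(barcodes, fill_value=0)
    total = dmso_total.sum()
    if total == 0:
        raise ValueError("DMSO control has no counts")
    f0 = dmso_total / total
    f0[f0 == 0] = 0.5 / total
    if f0_mode == "max_dmso":
        f0 = pd.Series(f0.max(), index=barcodes)

    gr = pd.DataFrame(index=barcodes, columns=reps, dtype=float)
    for rep in reps:
        fR = ts_by_replicate[rep].last_medium
        with np.errstate(divide="ignore"):
            r = np.log(fR / f0) / T
        r[fR == 0] = np.nan  # not detected in this medium series
        gr[rep] = r
    return classify_barcodes(gr)


@dataclass
class ConcordanceResult:
    """Agreement between the last medium sample and the harvested endpoint."""

    abs_diff: pd.Series  # per-barcode |last-medium freq - endpoint freq|
    rank_correlation: float  # Spearman rho over barcodes, NaN when undefined
    defined: bool  # False when the supports are disjoint / degenerate


def endpoint_concordance(ts: TrajectorySet) -> ConcordanceResult:
    """Compare the final medium composition to the harvested endpoint.

    Rank correlation (Spearman) is robust to the different sequencing
    depths of medium and harvested samples.  When the supports are
    disjoint or either vector is constant the correlation is undefined
    and flagged.
    """
    if (ts.endpoint_freq > 0).sum() == 0:
        raise ValueError("no barcode has nonzero endpoint frequency")
    last = ts.last_medium
    abs_diff = (last - ts.endpoint_freq).abs()
    joint = (last > 0) & (ts.endpoint_freq > 0)
    if joint.sum() < 2 or last.nunique() < 2 or ts.endpoint_freq.nunique() < 2:
        return ConcordanceResult(abs_diff=abs_diff, rank_correlation=float("nan"), defined=False)
    rho = stats.spearmanr(last, ts.endpoint_freq).statistic
    return ConcordanceResult(abs_diff=abs_diff, rank_correlation=float(rho), defined=bool(np.isfinite(rho)))
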
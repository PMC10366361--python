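"""Growth-rate-based phenotype classification of clone barcodes.

Each barcode's per-week growth rate in a drug-selected replicate is

    r = (1/T) * log(f_R / f_0)

where ``f_R`` is the barcode's frequency in the replicate endpoint,
``f_0`` its baseline frequency from the DMSO control, and ``T`` the
weeks between first drug treatment and harvest.  Barcodes expanding
(r > 0) in two or more replicates are called *pre-existing* resistant
(the same clone was selected independently in parallel arms), barcodes
expanding in exactly one replicate are *de novo*, and barcodes with
negative growth rate are *sensitive*.

Two baselines are supported: ``per_barcode_dmso`` compares each barcode
to its own DMSO frequency (barcodes absent from DMSO receive a
pseudo-frequency of 0.5 / total DMSO reads so de novo expansions remain
detectable); ``max_dmso`` uses the maximum barcode frequency of the
DMSO control as a single common baseline.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
import pandas as pd

from clonetrace.extract import CountMatrix

PRE_EXISTING = "pre-existing"
DE_NOVO = "de-novo"
SENSITIVE = "sensitive"

F0Mode = Literal["per_barcode_dmso", "max_dmso"]


def compute_frequencies(cm: CountMatrix) -> pd.DataFrame:
    """Within-sample barcode frequencies: each column normalized to sum 1."""
    col_sums = cm.counts.sum(axis=0)
    zero = col_sums[col_sums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return cm.counts / col_sums


def growth_rate(
    f_R: float, f_0: float, T: float, log_base: Literal["e", "10"] = "e"
) -> float:
    """Per-week log growth rate (1/T) * log(f_R / f_0).

    ``f_R = 0`` returns ``-inf`` (the barcode vanished by the endpoint).
    The sign is invariant to the log base.
    """
    if f_0 <= 0:
        raise ValueError("f_0 must be positive (apply the baseline policy first)")
    if T <= 0:
        raise ValueError("T must be positive")
    if f_R < 0:
        raise ValueError("f_R must be non-negative")
    if f_R == 0:
        return -math.inf
    log = math.log if log_base == "e" else math.log10
    return log(f_R / f_0) / T


def growth_rate_table(
    cm: CountMatrix,
    T: float = 26.0,
    f0_mode: F0Mode = "per_barcode_dmso",
    min_count: int = 2,
    log_base: Literal["e", "10"] = "e",
) -> pd.DataFrame:
    """Per-barcode, per-replicate growth rates from a filtered count matrix.

    A barcode is *detected* in a replicate when its count there reaches
    ``min_count``; undetected cells are NaN.  ``cm`` should already have
    passed :func:`clonetrace.extract.filter_low_counts`.
    """
    reps = cm.replicate_samples
    dmso = cm.dmso_samples
    if len(reps) < 2:
        raise ValueError("growth-rate classification needs >= 2 replicate samples")
    if len(dmso) != 1:
        raise ValueError(f"expected exactly one DMSO sample, found {len(dmso)}")
    freqs = compute_frequencies(cm)
    dmso_col = dmso[0]
    dmso_total = cm.counts[dmso_col].sum()
    if f0_mode == "per_barcode_dmso":
        f0 = freqs[dmso_col].copy()
        # pseudo-frequency of half a read for barcodes unseen in DMSO
        f0[f0 == 0] = 0.5 / dmso_total
    elif f0_mode == "max_dmso":
        f0 = pd.Series(freqs[dmso_col].max(), index=freqs.index)
    else:
        raise ValueError(f"unknown f0_mode: {f0_mode!r}")

    log = np.log if log_base == "e" else np.log10
    out = pd.DataFrame(index=freqs.index, columns=reps, dtype=float)
    for rep in reps:
        fR = freqs[rep]
        with np.errstate(divide="ignore"):
            r = log(fR / f0) / T
        r[cm.counts[rep] < min_count] = np.nan
        out[rep] = r
    return out


def classify_barcodes(gr: pd.DataFrame) -> pd.DataFrame:
    """Assign phenotype labels from a growth-rate table.

    For each barcode, the replicates where it is detected with r > 0 form
    its positive set P: |P| >= 2 labels every member pre-existing, |P| == 1
    labels that replicate de novo, and detected replicates with r <= 0 are
    sensitive (ties conservatively not treated as expansion).  Returns a
    long-format DataFrame (barcode_id, replicate, r, label) with one row
    per detected barcode-replicate cell.
    """
    if gr.shape[1] < 2:
        raise ValueError("classification needs >= 2 replicates")
    rows: list[tuple[int, str, float, str]] = []
    values = gr.to_numpy(dtype=float)
    for i, barcode in enumerate(gr.index):
        r_row = values[i]
        detected = ~np.isnan(r_row)
        n_positive = int((r_row[detected] > 0).sum())
        for j, rep in enumerate(gr.columns):
            if not detected[j]:
                continue
            r = r_row[j]
            if r > 0:
                label = PRE_EXISTING if n_positive >= 2 else DE_NOVO
            else:
                label = SENSITIVE
            rows.append((barcode, rep, r, label))
    return pd.DataFrame(rows, columns=["barcode_id", "replicate", "r", "label"])


def phenotype_frequency_summary(
    freqs: pd.DataFrame, calls: pd.DataFrame, replicate: str
) -> dict[str, float]:
    """Percent of a replicate's endpoint population in each phenotype.

    Sums the endpoint frequencies of the replicate's called barcodes per
    label and renormalizes over called barcodes so the three percentages
    sum to 100.
    """
    rep_calls = calls[calls["replicate"] == replicate]
    out = {PRE_EXISTING: 0.0, DE_NOVO: 0.0, SENSITIVE: 0.0}
    if rep_calls.empty:
        return out
    f = freqs.loc[rep_calls["barcode_id"], replicate].to_numpy()
    total = f.sum()
    if total == 0:
        return out
    for label in out:
        mask = (rep_calls["label"] == label).to_numpy()
        out[label] = float(100.0 * f[mask].sum() / total)
    return out


def unique_phenotype_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Distinct barcode counts per label and replicate.

    Returns a DataFrame indexed by replicate with columns
    ``n_pre_existing, n_de_novo, n_sensitive, n_total_detected``.
    """
    cols = {PRE_EXISTING: "n_pre_existing", DE_NOVO: "n_de_novo", SENSITIVE: "n_sensitive"}
    if calls.empty:
        return pd.DataFrame(
            columns=["n_pre_existing", "n_de_novo", "n_sensitive", "n_total_detected"]
        )
    rows = {}
    for rep, grp in calls.groupby("replicate"):
        row = {name: 0 for name in cols.values()}
        for label, sub in grp.groupby("label"):
            row[cols[str(label)]] = sub["barcode_id"].nunique()
        row["n_total_detected"] = grp["barcode_id"].nunique()
        rows[rep] = row
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return out[["n_pre_existing", "n_de_novo", "n_sensitive", "n_total_detected"]]
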
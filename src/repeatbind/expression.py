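"""Element-level expression quantification and activation analysis.

Reads are counted per element by exact-match (0-mismatch by default)
best-stratum alignment against the element sub-genome; counts are
normalized by each library's total mapped reads to a fixed denominator
(tags per ten million), and fold enrichments are taken relative to the
averaged normalized counts of the reference (empty-vector) libraries.

The activation analysis covers: the silent-element rule (reference mean
below a count cutoff with over a fold cutoff increase by any treatment),
paired t tests of treatment against reference, a per-condition
distribution-mean summary (mean fold with its standard error), treatment
concordance (correlation of log folds over silent elements, co-activated
set, subfamily breakdown).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chipseq import align_reads
from .simulate import FastqRead

__all__ = [
    "ExpressionError",
    "count_elements",
    "build_count_table",
    "normalize_counts",
    "fold_changes",
    "silent_set",
    "PairedTestResult",
    "paired_activation_test",
    "activation_summary",
    "ConcordanceResult",
    "concordance_analysis",
]


class ExpressionError(ValueError):
    pass


def count_elements(
    reads: Iterable[FastqRead],
    subgenome: Mapping[str, str],
    max_mismatches: int = 0,
) -> pd.Series:
    """Per-element read counts from exact-stratum alignment (one best hit/read)."""
    if not subgenome:
        raise ExpressionError("empty sub-genome")
    hits = align_reads(reads, subgenome, max_mismatches=max_mismatches)
    counts = hits["ref_id"].value_counts()
    keys = subgenome.ref_ids if hasattr(subgenome, "ref_ids") else list(subgenome.keys())
    return counts.reindex(keys, fill_value=0).rename("count")


def build_count_table(
    per_library: Mapping[str, pd.Series],
    elements: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the elements x libraries raw count table."""
    table = pd.DataFrame(per_library)
    table.index.name = "element_id"
    if elements is not None:
        table = table.reindex(elements["element_id"]).fillna(0)
    return table


def normalize_counts(
    raw: pd.DataFrame,
    library_totals: Mapping[str, float],
    denominator: float = 1e7,
) -> pd.DataFrame:
    """Scale each library to ``denominator`` total mapped reads."""
    out = raw.astype(float).copy()
    for lib in out.columns:
        total = float(library_totals[lib])
        if total <= 0:
            raise ExpressionError(f"library {lib!r} has non-positive total")
        out[lib] = out[lib] * (denominator / total)
    return out


def _condition_means(
    normalized: pd.DataFrame, condition_map: Mapping[str, str]
) -> pd.DataFrame:
    cond = pd.Series({lib: condition_map[lib] for lib in normalized.columns})
    return normalized.T.groupby(cond).mean().T


def fold_changes(
    normalized: pd.DataFrame,
    condition_map: Mapping[str, str],
    reference: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-condition fold enrichment vs the averaged reference libraries.

    Returns a frame with the reference mean (no pseudocount; used by the
    silent rule) and ``fold_<condition>`` columns computed with the
    pseudocount on both numerator and denominator.
    """
    ref_libs = [lib for lib, c in condition_map.items() if c == reference]
    if not ref_libs:
        raise ExpressionError(f"no libraries for reference condition {reference!r}")
    means = _condition_means(normalized, condition_map)
    ref_mean = normalized[ref_libs].mean(axis=1)
    out = pd.DataFrame({"ref_mean": ref_mean})
    for cond in means.columns:
        if cond == reference:
            continue
        out[f"fold_{cond}"] = (means[cond] + pseudocount) / (ref_mean + pseudocount)
    return out


def silent_set(
    folds: pd.DataFrame,
    count_cut: float = 10.0,
    fold_cut: float = 2.0,
) -> pd.Index:
    """Elements apparently silent in the reference yet induced by treatment.

    Selected when the (un-pseudocounted) reference mean normalized count is
    below ``count_cut`` and the maximum treatment fold exceeds ``fold_cut``.
    """
    fold_cols = [c for c in folds.columns if c.startswith("fold_")]
    if not fold_cols:
        raise ExpressionError("no treatment fold columns present")
    mask = (folds["ref_mean"] < count_cut) & (folds[fold_cols].max(axis=1) > fold_cut)
    return folds.index[mask]


@dataclass
class PairedTestResult:
    t: float
    p: float
    df: int
    mean_difference: float
    degenerate: bool = False


def paired_activation_test(
    normalized: pd.DataFrame,
    condition_map: Mapping[str, str],
    treatment: str,
    reference: str,
    log_scale: bool = True,
    two_tailed: bool = True,
) -> PairedTestResult:
    """Classic paired t test of treatment vs reference per element.

    Pairs are the per-element condition-mean normalized counts, on
    log2(x + 1) scale by default.  A zero-variance difference vector is
    reported as a degenerate case rather than a p-value.
    """
    means = _condition_means(normalized, condition_map)
    for c in (treatment, reference):
        if c not in means.columns:
            raise ExpressionError(f"condition {c!r} absent")
    x = means[treatment].to_numpy(float)
    y = means[reference].to_numpy(float)
    if log_scale:
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    d = x - y
    n = len(d)
    if n < 3:
        raise ExpressionError("need at least 3 paired elements")
    mean_d = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedTestResult(
            t=np.inf if mean_d != 0 else 0.0,
            p=np.nan if mean_d != 0 else 1.0,
            df=n - 1,
            mean_difference=float(mean_d),
            degenerate=mean_d != 0,
        )
    t = mean_d / (sd / np.sqrt(n))
    if two_tailed:
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    else:
        p = stats.t.sf(t, df=n - 1)
    return PairedTestResult(t=float(t), p=float(min(p, 1.0)), df=n - 1, mean_difference=float(mean_d))


def activation_summary(
    normalized: pd.DataFrame,
    condition_map: Mapping[str, str],
    reference: str,
    subset: pd.Index | None = None,
) -> pd.DataFrame:
    """Mean fold with SEM per condition over a subset of elements.

    The distribution-mean summary uses pseudocount-free per-element ratios
    of condition-mean to reference-mean normalized counts; elements with a
    zero reference mean are dropped (their ratio is undefined) and the
    retained count is reported.
    """
    means = _condition_means(normalized, condition_map)
    if subset is not None:
        means = means.loc[subset]
    ref = means[reference]
    keep = ref > 0
    rows = []
    for cond in means.columns:
        if cond == reference:
            continue
        ratio = (means.loc[keep, cond] / ref[keep]).to_numpy()
        rows.append(
            (cond, float(ratio.mean()), float(ratio.std(ddof=1) / np.sqrt(len(ratio))), len(ratio))
        )
    return pd.DataFrame(rows, columns=["condition", "mean_fold", "sem", "n"]).set_index("condition")


@dataclass
class ConcordanceResult:
    r: float
    n: int
    co_activated: pd.Index
    breakdown_full: pd.Series
    breakdown_co: pd.Series


def concordance_analysis(
    folds: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    subfamilies: pd.Series,
    fold_cut: float = 2.0,
    silent: pd.Index | None = None,
    count_cut: float = 10.0,
) -> ConcordanceResult:
    """Concordance of two treatments over the silent-element set.

    Pearson r of log2 folds over silent elements; the co-activated set is
    elements with fold >= ``fold_cut`` in both conditions; the subfamily
    breakdown gives proportions for the full input set and the co-activated
    set.
    """
    ca, cb = f"fold_{cond_a}", f"fold_{cond_b}"
    for c in (ca, cb):
        if c not in folds.columns:
            raise ExpressionError(f"missing column {c!r}")
    if silent is None:
        silent = folds.index[folds["ref_mean"] < count_cut]
    sub = folds.loc[silent]
    if len(sub) < 3:
        raise ExpressionError("fewer than 3 elements in the silent set")
    la = np.log2(sub[ca].to_numpy())
    lb = np.log2(sub[cb].to_numpy())
    r = float(np.corrcoef(la, lb)[0, 1])
    co = sub.index[(sub[ca] >= fold_cut) & (sub[cb] >= fold_cut)]
    fam = subfamilies.reindex(folds.index)
    breakdown_full = fam.value_counts(normalize=True).sort_index()
    breakdown_co = (
        fam.loc[co].value_counts(normalize=True).reindex(breakdown_full.index).fillna(0.0)
        if len(co)
        else breakdown_full * 0.0
    )
    return ConcordanceResult(
        r=r, n=len(sub), co_activated=co, breakdown_full=breakdown_full, breakdown_co=breakdown_co
    )
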
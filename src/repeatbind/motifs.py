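"""Position-weight-matrix discovery and cluster-site (staggered) detection.

``learn_pwm_oops`` fits the one-occurrence-per-sequence (OOPS) model by EM:
every sequence contains exactly one site of fixed width, uniformly placed
over positions and (optionally) both strands.  Multiple seedings from
high-frequency w-mers guard against local optima; the per-iteration training
log-likelihood is checked to be non-decreasing (an EM invariant).

Sites are scored by log2 odds against the 0-order background; exact
p-values come from a dynamic-programming convolution of the
integer-discretised per-column score distributions.

``detect_staggered_duplication`` asks whether a long consensus contains two
offset copies of a short one — the signature by which tandem repeats build
cluster binding sites out of a single short site — by sliding the short
matrix over the long one (both orientations) and correlating columns.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dnautil import BASES, encode, revcomp

__all__ = [
    "PWM",
    "MotifError",
    "learn_pwm_oops",
    "score_site",
    "score_distribution",
    "site_pvalue",
    "scan_sequences",
    "StaggerResult",
    "detect_staggered_duplication",
    "pwm_to_meme",
]


class MotifError(ValueError):
    pass


@dataclass
class PWM:
    """Column-stochastic base-probability matrix with its background."""

    matrix: np.ndarray            # (w, 4), rows sum to 1
    background: np.ndarray        # (4,)
    log_likelihood: float = np.nan
    ll_history: np.ndarray = field(default_factory=lambda: np.array([]))
    #: penalized (MAP) objective per iteration; non-decreasing by construction
    objective_history: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.background = np.asarray(self.background, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise MotifError("matrix must be (w, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise MotifError("matrix columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1].copy(), self.background.copy(), self.log_likelihood)


def _windows(codes: np.ndarray, w: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(codes, w)


def _background(seq_codes: Sequence[np.ndarray]) -> np.ndarray:
    counts = np.zeros(4)
    for c in seq_codes:
        counts += np.bincount(c, minlength=4)[:4]
    return counts / counts.sum()


def _seed_pwm(kmer_codes: np.ndarray, background: np.ndarray) -> np.ndarray:
    w = len(kmer_codes)
    mat = np.full((w, 4), 0.15)
    mat[np.arange(w), kmer_codes] = 0.55
    return mat


def learn_pwm_oops(
    sequences: Sequence[str],
    w: int,
    n_starts: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
    revcomp_model: bool = True,
    pseudocount: float = 0.25,
) -> PWM:
    """EM fit of the OOPS motif model at fixed width, both strands.

    Seedings are taken from the ``n_starts`` most frequent w-mers of the
    input (ties broken lexicographically), making the fit deterministic.
    Returns the PWM of the best seeding by training log-likelihood.
    """
    if len(sequences) < 2:
        raise MotifError("need at least 2 sequences")
    seq_codes = []
    for s in sequences:
        if len(s) < w:
            raise MotifError(f"sequence of length {len(s)} shorter than width {w}")
        c = encode(s)
        if (c > 3).any():
            raise MotifError("sequences must be ACGT only")
        seq_codes.append(c)
    background = _background(seq_codes)
    log_bg = np.log(background)

    # high-frequency w-mer seeds
    kmer_counts: dict[str, int] = {}
    for s in sequences:
        for i in range(len(s) - w + 1):
            kmer = s[i : i + w]
            kmer_counts[kmer] = kmer_counts.get(kmer, 0) + 1
    seeds = sorted(kmer_counts, key=lambda km: (-kmer_counts[km], km))[:n_starts]
    if not seeds:
        raise MotifError("no seed w-mers available")

    windows = [_windows(c, w) for c in seq_codes]
    win_bg = [log_bg[wn].sum(axis=1) for wn in windows]

    best: PWM | None = None
    for seed in seeds:
        mat = _seed_pwm(encode(seed), background)
        obj_prev = -np.inf
        history = []
        obj_hist = []
        for _ in range(max_iter):
            log_mat = np.log(mat)
            log_mat_rc = np.log(mat[::-1, ::-1])
            counts = np.full((w, 4), pseudocount)
            ll = 0.0
            col_idx = np.arange(w)
            for wn, bg_sc in zip(windows, win_bg):
                sc_f = log_mat[col_idx, wn].sum(axis=1)
                if revcomp_model:
                    sc_r = log_mat_rc[col_idx, wn].sum(axis=1)
                    lo = np.concatenate([sc_f, sc_r]) - np.concatenate([bg_sc, bg_sc])
                else:
                    lo = sc_f - bg_sc
                m = lo.max()
                weights = np.exp(lo - m)
                z = weights.sum()
                gamma = weights / z
                ll += m + np.log(z) - np.log(len(lo))  # + log bg(seq), a constant
                n_pos = wn.shape[0]
                gf = gamma[:n_pos]
                np.add.at(counts, (col_idx[None, :], wn), gf[:, None])
                if revcomp_model:
                    gr = gamma[n_pos:]
                    rc_wn = 3 - wn[:, ::-1]
                    np.add.at(counts, (col_idx[None, :], rc_wn), gr[:, None])
            # MAP-EM with a Dirichlet pseudocount prior: the monotone
            # quantity is the penalized objective, not the raw likelihood
            obj = ll + pseudocount * np.log(mat).sum()
            mat = counts / counts.sum(axis=1, keepdims=True)
            history.append(ll)
            obj_hist.append(obj)
            if obj + 1e-8 < obj_prev:
                raise MotifError("EM objective decreased; numerical failure")
            if obj - obj_prev < tol:
                break
            obj_prev = obj
        cand = PWM(
            mat,
            background,
            log_likelihood=history[-1],
            ll_history=np.array(history),
            objective_history=np.array(obj_hist),
        )
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    return best


# ---------------------------------------------------------------------------
# scoring


def score_site(pwm: PWM, site: str) -> float:
    """Log2-odds score of one site; N bases score at background (0)."""
    if len(site) != pwm.width:
        raise MotifError(f"site length {len(site)} != width {pwm.width}")
    codes = encode(site)
    score = 0.0
    for i, c in enumerate(codes):
        if c > 3:
            continue  # N: background, contributes 0
        score += np.log2(pwm.matrix[i, c] / pwm.background[c])
    return float(score)


def _score_table(pwm: PWM, step: float) -> np.ndarray:
    """Integer-discretised per-column log2-odds (w, 4)."""
    with np.errstate(divide="ignore"):
        lo = np.log2(pwm.matrix / pwm.background[None, :])
    return np.round(lo / step).astype(np.int64)


def score_distribution(pwm: PWM, step: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of discretised scores under the background.

    Returns (integer score lattice values, probabilities), computed by
    column-wise convolution.
    """
    table = _score_table(pwm, step)
    lo_min = int(table.min(axis=1).sum())
    lo_max = int(table.max(axis=1).sum())
    base = -min(lo_min, 0)  # index of lattice score 0
    size = base + max(lo_max, 0) + 1
    dist = np.zeros(size)
    dist[base] = 1.0
    for i in range(pwm.width):
        new = np.zeros_like(dist)
        for c in range(4):
            k = int(table[i, c])
            p = pwm.background[c]
            if k == 0:
                new += p * dist
            elif k > 0:
                new[k:] += p * dist[:-k]
            else:
                new[:k] += p * dist[-k:]
        dist = new
    values = np.arange(size) - base
    keep = dist > 0
    return values[keep], dist[keep]


def site_pvalue(pwm: PWM, score: float | None = None, site: str | None = None,
                step: float = 0.01) -> float:
    """Exact p-value P(score' >= score) under the 0-order background.

    When ``site`` is given the threshold is the site's own lattice score
    (per-column rounding), which matches exhaustive enumeration exactly;
    otherwise the float ``score`` is rounded onto the lattice.
    """
    if site is not None:
        table = _score_table(pwm, step)
        codes = encode(site)
        t = int(sum(int(table[i, c]) for i, c in enumerate(codes) if c <= 3))
    elif score is not None:
        t = int(round(score / step))
    else:
        raise MotifError("give a score or a site")
    values, probs = score_distribution(pwm, step)
    p = float(probs[values >= t].sum())
    return min(max(p, 0.0), 1.0) if p > 0 else float(probs[values >= values.max()].sum())


def scan_sequences(
    pwm: PWM,
    sequences: dict,
    step: float = 0.01,
    max_pvalue: float = 1e-3,
) -> "list[tuple]":
    """All sites with p <= max_pvalue on either strand.

    Returns (sequence_id, offset, strand, score, p) tuples sorted by
    (sequence_id, offset).
    """
    values, probs = score_distribution(pwm, step)
    tail = np.cumsum(probs[::-1])[::-1]
    table = _score_table(pwm, step)
    out = []
    w = pwm.width
    col = np.arange(w)
    for seq_id, seq in sequences.items():
        codes = encode(seq)
        if len(codes) < w:
            continue
        for strand in ("+", "-"):
            cc = codes if strand == "+" else encode(revcomp(seq))
            wn = _windows(cc, w)
            lat = table[col, wn].sum(axis=1)
            idx = np.searchsorted(values, lat)
            idx = np.clip(idx, 0, len(values) - 1)
            pv = tail[idx]
            for j in np.nonzero(pv <= max_pvalue)[0]:
                off = int(j) if strand == "+" else len(seq) - w - int(j)
                score = float(lat[j] * step)
                out.append((seq_id, off, strand, score, float(pv[j])))
    out.sort(key=lambda r: (r[0], r[1], r[2]))
    return out


# ---------------------------------------------------------------------------
# staggered duplication


@dataclass
class StaggerResult:
    similarities: np.ndarray      # best-orientation similarity per offset
    orientations: list            # "+" or "-" per offset
    offsets: tuple | None         # (o1, o2) of the detected pair
    is_duplicated: bool
    unit_estimate: int | None     # o2 - o1, the implied tandem period

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.is_duplicated


def _column_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-column Pearson correlation of two equal-width matrices."""
    sims = []
    for i in range(a.shape[0]):
        x, y = a[i], b[i]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            sims.append(0.0)
        else:
            sims.append(float(np.corrcoef(x, y)[0, 1]))
    return float(np.mean(sims))


def detect_staggered_duplication(
    pwm_short: PWM,
    pwm_long: PWM,
    s_min: float = 0.8,
    d_min: int | None = None,
) -> StaggerResult:
    """Find two offset copies of the short consensus inside the long one.

    Similarity at offset o is the mean per-column Pearson correlation of the
    short matrix (forward or reverse-complement orientation, whichever is
    higher) with the long matrix columns [o, o + ws).  Duplication is called
    when two offsets at least ``d_min`` apart (default half the short width)
    both reach ``s_min``.
    """
    ws, wl = pwm_short.width, pwm_long.width
    if wl <= ws:
        raise MotifError("long PWM must be wider than the short PWM")
    if d_min is None:
        d_min = ws // 2
    short_f = pwm_short.matrix
    short_r = pwm_short.reverse_complement().matrix
    sims = np.empty(wl - ws + 1)
    orients = []
    for o in range(wl - ws + 1):
        block = pwm_long.matrix[o : o + ws]
        sf = _column_similarity(short_f, block)
        sr = _column_similarity(short_r, block)
        if sf >= sr:
            sims[o], orient = sf, "+"
        else:
            sims[o], orient = sr, "-"
        orients.append(orient)
    hits = np.nonzero(sims >= s_min)[0]
    best_pair = None
    best_sum = -np.inf
    for ii in range(len(hits)):
        for jj in range(ii + 1, len(hits)):
            o1, o2 = int(hits[ii]), int(hits[jj])
            if o2 - o1 >= d_min and sims[o1] + sims[o2] > best_sum:
                best_sum = sims[o1] + sims[o2]
                best_pair = (o1, o2)
    return StaggerResult(
        similarities=sims,
        orientations=orients,
        offsets=best_pair,
        is_duplicated=best_pair is not None,
        unit_estimate=(best_pair[1] - best_pair[0]) if best_pair else None,
    )


def pwm_to_meme(pwm: PWM, name: str = "motif") -> str:
    """Minimal MEME-format text block (frequency matrix)."""
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.4f}" for b, f in zip(BASES, pwm.background)),
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pwm.width}",
    ]
    for row in pwm.matrix:
        lines.append(" " + " ".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"
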
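"""Short-read alignment to repeat sub-genomes, enrichment, and metaprofiles.

The aligner is deliberately minimal: ungapped end-to-end alignment of
fixed-length reads against a sub-genome, exact k-mer seeds with pigeonhole
placement (``max_mismatches + 1`` disjoint seeds guarantee every hit within
the mismatch budget produces at least one exact seed), mismatch counting on
both strands, best-stratum filtering (only minimum-mismatch hits), and a
deterministic tie-break: lexicographic reference id, then position, then
forward strand first.  A percent-identity threshold maps to a mismatch
budget of ``floor(read_length * (1 - min_identity))``.

Downstream: tile-level tag densities (per ten million mapped reads), the
cross-platform validation rule (a ChIP-array-positive repeat is validated if
any of its tiles is enriched at least ``min_fold`` in every sequencing
replicate of the implicated protein(s)), binned tag-density metaprofiles
along elements, and a k-means estimate of the occupied element fraction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Tile
from .chipchip import OccupancyCall
from .dnautil import encode, revcomp
from .simulate import FastqRead

__all__ = [
    "AlignmentError",
    "SubgenomeIndex",
    "align_reads",
    "hits_to_sam",
    "quantify_tiles",
    "validate_calls",
    "metaprofile",
    "profile_matrix",
    "occupancy_fraction",
]

HIT_COLUMNS = ["read_id", "ref_id", "pos", "strand", "mismatches", "identity"]


class AlignmentError(ValueError):
    pass


class SubgenomeIndex:
    """Sorted k-mer index over the concatenated reference sequences."""

    def __init__(self, refs: Mapping[str, str], seed_length: int = 16):
        if not refs:
            raise AlignmentError("empty sub-genome")
        if not (4 <= seed_length <= 31):
            raise AlignmentError("seed_length must be in [4, 31]")
        self.seed_length = seed_length
        self.ref_ids = list(refs.keys())
        self.ref_lengths = np.array([len(refs[r]) for r in self.ref_ids], dtype=np.int64)
        self.ref_starts = np.concatenate([[0], np.cumsum(self.ref_lengths)])
        # lexicographic rank per reference, for the deterministic tie-break
        self.ref_rank = np.empty(len(self.ref_ids), dtype=np.int64)
        for rank, ri in enumerate(sorted(range(len(self.ref_ids)), key=lambda i: self.ref_ids[i])):
            self.ref_rank[ri] = rank
        self.codes = np.concatenate([encode(refs[r]) for r in self.ref_ids])
        self._mults = (4 ** np.arange(seed_length - 1, -1, -1, dtype=np.uint64))
        self._build()

    def _build(self) -> None:
        k = self.seed_length
        codes = self.codes
        n = len(codes) - k + 1
        if n <= 0:
            raise AlignmentError("reference shorter than the seed length")
        kmers = np.zeros(n, dtype=np.uint64)
        valid = np.ones(n, dtype=bool)
        for j in range(k):
            col = codes[j : j + n]
            kmers = (kmers << np.uint64(2)) | (col & np.uint8(3)).astype(np.uint64)
            valid &= col <= 3
        self.positions = np.nonzero(valid)[0].astype(np.int64)
        order = np.argsort(kmers[self.positions], kind="stable")
        self.positions = self.positions[order]
        self.sorted_kmers = kmers[self.positions]

    def lookup(self, kmer: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted_kmers, np.uint64(kmer), side="left")
        hi = np.searchsorted(self.sorted_kmers, np.uint64(kmer), side="right")
        return self.positions[lo:hi]

    def locate(self, concat_pos: int) -> tuple[int, int]:
        """Concatenated position -> (reference index, local position)."""
        ri = int(np.searchsorted(self.ref_starts, concat_pos, side="right")) - 1
        return ri, int(concat_pos - self.ref_starts[ri])


def align_reads(
    reads: Iterable[FastqRead],
    refs: Mapping[str, str],
    max_mismatches: int | None = None,
    min_identity: float | None = None,
    seed_length: int = 16,
) -> pd.DataFrame:
    """Best-stratum ungapped alignment; one hit per read, deterministic ties.

    Exactly one of ``max_mismatches`` / ``min_identity`` must be given.
    Returns a DataFrame with read_id, ref_id, pos (0-based on the forward
    reference), strand, mismatches and identity fraction.
    """
    if (max_mismatches is None) == (min_identity is None):
        raise AlignmentError("set exactly one of max_mismatches / min_identity")
    index = refs if isinstance(refs, SubgenomeIndex) else SubgenomeIndex(refs, seed_length)
    k = index.seed_length
    rows = []
    for read in reads:
        seq = read.sequence
        length = len(seq)
        if max_mismatches is not None:
            budget = max_mismatches
        else:
            budget = int(np.floor(length * (1.0 - min_identity) + 1e-9))
        n_seeds = budget + 1
        eff_k = k if n_seeds * k <= length else max(4, length // n_seeds)
        if eff_k > length:
            raise AlignmentError(f"read {read.name!r} shorter than the seed")
        if eff_k != k:
            # narrower seeds than the index provides: fall back to index k if
            # possible, otherwise the pigeonhole guarantee needs eff_k-mers
            raise AlignmentError(
                f"read {read.name!r}: {n_seeds} seeds of {k} bases do not fit; "
                "use a smaller seed_length"
            )
        best: tuple | None = None  # (mm, ref_rank, pos, strand_rank, ref_id)
        span = np.arange(length)
        for strand_rank, (strand, s) in enumerate((("+", seq), ("-", revcomp(seq)))):
            codes = encode(s)
            if (codes > 3).any():
                continue
            cand_parts = []
            for off in range(0, n_seeds * k, k):
                v = int(np.dot(codes[off : off + k].astype(np.uint64), index._mults))
                hits_at = index.lookup(v)
                if len(hits_at):
                    cand_parts.append(hits_at - off)
            if not cand_parts:
                continue
            cand = np.unique(np.concatenate(cand_parts))
            cand = cand[cand >= 0]
            if not len(cand):
                continue
            ri = np.searchsorted(index.ref_starts, cand, side="right") - 1
            local = cand - index.ref_starts[ri]
            ok = local + length <= index.ref_lengths[ri]
            cand, ri, local = cand[ok], ri[ok], local[ok]
            if not len(cand):
                continue
            windows = index.codes[cand[:, None] + span[None, :]]
            mm = (windows != codes[None, :]).sum(axis=1)
            keep = mm <= budget
            for j in np.nonzero(keep)[0]:
                key = (int(mm[j]), int(index.ref_rank[ri[j]]), int(local[j]), strand_rank)
                if best is None or key < best[:4]:
                    best = key + (index.ref_ids[int(ri[j])],)
        if best is not None:
            rows.append(
                (
                    read.name,
                    best[4],
                    best[2],
                    "+" if best[3] == 0 else "-",
                    best[0],
                    (length - best[0]) / length,
                )
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def hits_to_sam(hits: pd.DataFrame, refs: Mapping[str, str], read_length: int, stream) -> None:
    """Minimal SAM output (QNAME/FLAG/RNAME/POS/MAPQ/CIGAR plus NM tag)."""
    stream.write("@HD\tVN:1.6\tSO:unknown\n")
    for rid, seq in refs.items():
        stream.write(f"@SQ\tSN:{rid}\tLN:{len(seq)}\n")
    for row in hits.itertuples(index=False):
        flag = 0 if row.strand == "+" else 16
        stream.write(
            f"{row.read_id}\t{flag}\t{row.ref_id}\t{row.pos + 1}\t255\t"
            f"{read_length}M\t*\t0\t0\t*\t*\tNM:i:{row.mismatches}\n"
        )


# ---------------------------------------------------------------------------
# enrichment quantification


def _read_centers(hits: pd.DataFrame, read_length: int) -> pd.DataFrame:
    out = hits.copy()
    out["center"] = out["pos"] + read_length // 2
    return out


def quantify_tiles(
    hits_chip: pd.DataFrame,
    hits_input: pd.DataFrame,
    tiles: Sequence[Tile],
    read_length: int = 50,
    total_chip: int | None = None,
    total_input: int | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Tile tag densities (tags per ten million mapped reads) and ratios.

    Read centers are assigned to the tile window on the tile's parent
    reference; densities are normalized by each library's mapped-read total
    (override with ``total_chip``/``total_input`` when the library extends
    beyond the quantified sub-genome); the ratio carries a pseudocount on
    both densities.
    """
    if hits_chip.empty or hits_input.empty:
        raise AlignmentError("both chip and input hit sets must be non-empty")
    total_chip = total_chip if total_chip is not None else len(hits_chip)
    total_input = total_input if total_input is not None else len(hits_input)
    rows = []
    chip = _read_centers(hits_chip, read_length)
    inp = _read_centers(hits_input, read_length)
    chip_by_ref = dict(tuple(chip.groupby("ref_id")))
    inp_by_ref = dict(tuple(inp.groupby("ref_id")))

    def _count(by_ref, ref, lo, hi):
        sub = by_ref.get(ref)
        if sub is None:
            return 0
        c = sub["center"].to_numpy()
        return int(((c >= lo) & (c < hi)).sum())

    for t in tiles:
        if t.repeat_id is None:
            continue
        lo, hi = t.offset, t.offset + len(t.sequence)
        nc = _count(chip_by_ref, t.repeat_id, lo, hi)
        ni = _count(inp_by_ref, t.repeat_id, lo, hi)
        dc = nc * 1e7 / total_chip
        di = ni * 1e7 / total_input
        rows.append((t.tile_id, t.repeat_id, nc, ni, dc, di, (dc + pseudocount) / (di + pseudocount)))
    return pd.DataFrame(
        rows,
        columns=["tile_id", "repeat_id", "chip_count", "input_count", "chip_density", "input_density", "ratio"],
    )


def validate_calls(
    calls: Sequence[OccupancyCall],
    enrichment: Mapping[str, Sequence[pd.DataFrame]],
    min_fold: float = 2.0,
) -> list[OccupancyCall]:
    """Apply the cross-platform validation rule in place and return the calls.

    ``enrichment`` maps protein label -> list of per-replicate tile
    enrichment tables.  A repeat is validated when, for every protein
    implicated by its class, at least one of its tiles has ratio >=
    ``min_fold`` in all of that protein's replicates.
    """
    implicated = {"CO_BOUND": ("A", "B"), "A_ONLY": ("A",), "B_ONLY": ("B",)}
    ratio = {}
    for prot, tables in enrichment.items():
        if not tables:
            continue
        mats = []
        for tab in tables:
            mats.append(tab.set_index("tile_id")["ratio"])
        ratio[prot] = pd.concat(mats, axis=1)
    repeat_tiles: dict[str, list[str]] = {}
    any_table = next(iter(enrichment.values()))[0]
    for row in any_table.itertuples(index=False):
        repeat_tiles.setdefault(row.repeat_id, []).append(row.tile_id)
    for call in calls:
        prots = implicated.get(call.occupancy_class)
        if prots is None:
            call.validated = None
            continue
        missing = [p for p in prots if p not in ratio]
        if missing:
            raise AlignmentError(
                f"{call.repeat_id}: class {call.occupancy_class} implicates protein(s) "
                f"{missing} with no sequencing data"
            )
        ok = True
        for p in prots:
            tiles = repeat_tiles.get(call.repeat_id, [])
            mat = ratio[p].reindex(tiles)
            ok &= bool((mat >= min_fold).all(axis=1).any())
        call.validated = ok
    return list(calls)


# ---------------------------------------------------------------------------
# metaprofiles and occupancy fraction


def metaprofile(
    hits: pd.DataFrame,
    elements: Sequence[tuple],
    bin_width: int = 50,
    read_length: int = 50,
    total_mapped: int | None = None,
    smooth: bool = True,
) -> pd.DataFrame:
    """Aggregated binned tag density along a family of elements.

    ``elements`` are (ref_id, start, end) intervals on the aligned
    references.  Read centers are binned from each element's start; raw bin
    counts are normalized per ten million mapped reads and divided by the
    number of elements contributing to each bin.  The ``smooth`` column is a
    centered 3-bin moving average (the fit-line analog).
    """
    if not elements:
        raise AlignmentError("no elements supplied")
    for _, start, end in elements:
        if end - start < bin_width:
            raise AlignmentError("element shorter than the bin width")
    total_mapped = total_mapped if total_mapped is not None else max(len(hits), 1)
    n_bins = max((end - start) // bin_width for _, start, end in elements)
    raw = np.zeros(n_bins)
    contributing = np.zeros(n_bins)
    centers = _read_centers(hits, read_length) if not hits.empty else hits.assign(center=[])
    by_ref = dict(tuple(centers.groupby("ref_id"))) if not hits.empty else {}
    for ref_id, start, end in elements:
        nb = (end - start) // bin_width
        contributing[:nb] += 1
        sub = by_ref.get(ref_id)
        if sub is None:
            continue
        c = sub["center"].to_numpy()
        c = c[(c >= start) & (c < start + nb * bin_width)]
        if len(c) == 0:
            continue
        b = (c - start) // bin_width
        np.add.at(raw, b, 1)
    density = raw * 1e7 / total_mapped / np.maximum(contributing, 1)
    out = pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "start": np.arange(n_bins) * bin_width,
            "raw_count": raw,
            "n_elements": contributing,
            "density": density,
        }
    )
    if smooth:
        out["smooth"] = (
            out["density"].rolling(window=3, center=True, min_periods=1).mean()
        )
    return out


def profile_matrix(
    hits: pd.DataFrame,
    elements: Sequence[tuple],
    n_bins: int = 25,
    read_length: int = 50,
    total_mapped: int | None = None,
) -> tuple[np.ndarray, list]:
    """Per-element relative-position profile matrix (elements x n_bins)."""
    if not elements:
        raise AlignmentError("no elements supplied")
    total_mapped = total_mapped if total_mapped is not None else max(len(hits), 1)
    centers = _read_centers(hits, read_length) if not hits.empty else None
    by_ref = dict(tuple(centers.groupby("ref_id"))) if centers is not None else {}
    mat = np.zeros((len(elements), n_bins))
    ids = []
    for i, (ref_id, start, end) in enumerate(elements):
        ids.append(ref_id)
        sub = by_ref.get(ref_id)
        if sub is None:
            continue
        c = sub["center"].to_numpy()
        c = c[(c >= start) & (c < end)]
        if len(c) == 0:
            continue
        b = ((c - start) * n_bins // (end - start)).astype(int)
        np.add.at(mat[i], b, 1)
    return mat * 1e7 / total_mapped, ids


def occupancy_fraction(
    profiles: np.ndarray,
    enrichment: np.ndarray,
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
    occupied_min_enrichment: float = 2.0,
) -> tuple[float, np.ndarray, pd.DataFrame]:
    """k-means ranked clustering of element tag-density profiles.

    Rows are capped at the matrix 99th percentile before clustering;
    clusters are ranked by their mean chip/input enrichment and elements in
    clusters at or above ``occupied_min_enrichment`` are counted occupied.
    Returns (fraction, per-element cluster rank, cluster summary).
    """
    from sklearn.cluster import KMeans

    profiles = np.asarray(profiles, float)
    enrichment = np.asarray(enrichment, float)
    if k < 2:
        raise AlignmentError("k must be >= 2")
    if profiles.shape[0] < k:
        raise AlignmentError("need at least k elements")
    cap = np.percentile(profiles, 99)
    capped = np.minimum(profiles, cap) if cap > 0 else profiles
    if np.allclose(capped, capped[0]):
        # degenerate: all profiles identical; nothing can be called occupied
        labels = np.zeros(profiles.shape[0], dtype=int)
        mean_enr = np.array([enrichment.mean()])
        occupied = mean_enr >= occupied_min_enrichment
        frac = float(occupied[labels].mean()) if occupied.any() else 0.0
        summary = pd.DataFrame({"cluster": [0], "n": [len(labels)], "mean_enrichment": mean_enr})
        return frac, labels, summary
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(capped)
    means = np.array([enrichment[raw_labels == c].mean() if (raw_labels == c).any() else -np.inf
                      for c in range(k)])
    rank_of = {c: r for r, c in enumerate(np.argsort(-means))}  # rank 0 = most enriched
    labels = np.array([rank_of[c] for c in raw_labels])
    ranked_means = np.array([means[c] for c in np.argsort(-means)])
    occupied_mask = np.array([ranked_means[r] >= occupied_min_enrichment for r in labels])
    summary = pd.DataFrame(
        {
            "cluster": np.arange(k),
            "n": [(labels == r).sum() for r in range(k)],
            "mean_enrichment": ranked_means,
        }
    )
    return float(occupied_mask.mean()), labels, summary
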
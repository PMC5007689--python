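"""Synthetic repeat genomes with planted occupancy, array, read, and count data.

The generator emits everything the downstream analyses consume, together with
machine-readable ground truth:

* a genome containing simple tandem repeats whose unit embeds a short
  GC-rich binding consensus (so that consecutive units create a staggered
  cluster of sites), SVA-like composite elements (hexamer - Alu-like - VNTR -
  SINE-R-like - polyA, with two juxtaposed sites in each VNTR unit),
  alphoid-like 171-bp arrays (a configurable fraction carrying a
  CENP-B-box-like 17-mer), and random background;
* per-base protein affinity tracks encoding three planted occupancy classes
  (co-bound / A-only / B-only) plus unbound background;
* two-channel array intensities per tile per replicate, with a shared
  per-tile trend (the first-principal-component analog), an
  intensity-dependent dye-bias curve, per-array channel multipliers
  (which make control-feature centering necessary), and log-normal noise;
* single-end reads with fragments in a configurable size range, sampled
  proportionally to affinity (ChIP mode) or uniformly (input mode);
* element-level RNA-seq count tables across conditions, with a silent
  baseline, per-condition mean activation folds, and a shared latent factor
  producing a target correlation between treatments.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config, so a fixed config reproduces byte-identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .catalog import RepeatRecord, Tile, tile_catalogue, write_fasta
from .dnautil import decode, encode, mutate, random_seq, revcomp

__all__ = [
    "SimConfig",
    "SyntheticGenome",
    "GroundTruth",
    "ElementRecord",
    "FastqRead",
    "generate_repeat_genome",
    "simulate_array",
    "simulate_reads",
    "simulate_rnaseq_counts",
    "simulate_sam_matrix",
    "write_fastq",
]

#: default planted short binding consensus (GC-rich 20-mer, core site)
DEFAULT_CONSENSUS = "GCGCCCCCTGGTGGCCACAG"

#: CENP-B-box-like 17-mer planted in a subset of alphoid-like units
CENPB_BOX_LIKE = "TTCGTTGGAAACGGGAT"

CHROM = "synth1"

OCC_CLASSES = ("CO_BOUND", "A_ONLY", "B_ONLY", "NONE")


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RepeatMix:
    """Counts and structure of the planted simple tandem repeats."""

    n_cobound: int = 40
    n_a_only: int = 15
    n_b_only: int = 15
    n_background: int = 1000
    unit_length: int = 25
    units: int = 8
    consensus: str = DEFAULT_CONSENSUS
    site_mutation_rate: float = 0.05


@dataclass
class SvaConfig:
    """SVA-like composite elements; region order is fixed by construction."""

    n_elements: int = 100
    occupied_fraction: float = 0.7
    hexamer_copies: int = 12
    alu_length: int = 300
    vntr_copies_min: int = 6
    vntr_copies_max: int = 12
    vntr_pad: int = 9
    siner_length: int = 400
    polya_length: int = 25
    #: per-element divergence from the family canonical; high enough that
    #: most read-length windows are element-unique under exact alignment
    divergence: float = 0.06
    vntr_affinity: float = 8.0
    subfamily_props: tuple = (
        ("SVA_A", 0.05),
        ("SVA_B", 0.08),
        ("SVA_C", 0.12),
        ("SVA_D", 0.35),
        ("SVA_E", 0.25),
        ("SVA_F", 0.15),
    )


@dataclass
class AlphoidConfig:
    n_arrays: int = 6
    units: int = 6
    unit_length: int = 171
    cenpb_fraction: float = 0.5
    cenpb_offset: int = 30
    divergence: float = 0.05
    planted_class: str = "NONE"


@dataclass
class OccupancyLevels:
    """Linear affinity relative to background for the planted classes.

    ``enriched`` must sit well above the 4x calling threshold and
    ``depleted`` below 1x so that the all-replicates class rules are
    satisfiable under the default array noise.
    """

    background: float = 1.0
    enriched: float = 8.0
    depleted: float = 0.7


@dataclass
class ArrayConfig:
    replicates: int = 3
    noise_log2_sd: float = 0.1
    #: cubic dye-bias coefficients applied to centred log-intensity (A - mean)
    dye_bias: tuple = (0.25, 0.08, -0.02)
    #: sd of the per-tile log2 offset shared by every array (PC1-analog trend)
    trend_log2_sd: float = 0.25
    #: sd of per-array per-channel global log2 multipliers (removed by centering)
    channel_log2_sd: float = 0.5
    base_intensity: float = 500.0
    copy_log2_sd: float = 1.2


@dataclass
class ReadConfig:
    read_length: int = 50
    fragment_min: int = 300
    fragment_max: int = 500
    error_rate: float = 0.0


@dataclass
class RnaSeqCondition:
    name: str
    mean_fold: float
    is_reference: bool = False


@dataclass
class RnaSeqConfig:
    """Element-level count model for the knockdown / drug conditions.

    Silent elements draw a baseline expectation below the silent cutoff and
    respond to treatments with log-normal fold effects; already-expressed
    elements do not change.  A latent factor shared across the conditions in
    ``latent_group`` produces the target correlation of planted log-folds.
    """

    n_elements: int = 2000
    silent_fraction: float = 0.85
    silent_base_range: tuple = (2.0, 9.0)
    expressed_base_range: tuple = (50.0, 300.0)
    log2_fold_sd: float = 0.5
    latent_corr: float = 0.8
    latent_group: tuple = ("boris_kd", "dznep", "kd_dznep")
    n_libraries: int = 4
    library_total: float = 1e8
    denominator: float = 1e7
    conditions: tuple = (
        RnaSeqCondition("empty_vector", 1.0, is_reference=True),
        RnaSeqCondition("boris_kd", 1.03),
        RnaSeqCondition("dznep", 1.37),
        RnaSeqCondition("kd_dznep", 1.55),
    )


@dataclass
class SimConfig:
    seed: int = 1
    background_length: int = 600_000
    gc: float = 0.41
    tile_length: int = 50
    n_control_tiles: int = 500
    min_spacer: int = 60
    repeats: RepeatMix = field(default_factory=RepeatMix)
    sva: SvaConfig = field(default_factory=SvaConfig)
    alphoid: AlphoidConfig = field(default_factory=AlphoidConfig)
    occupancy: OccupancyLevels = field(default_factory=OccupancyLevels)
    array: ArrayConfig = field(default_factory=ArrayConfig)
    reads: ReadConfig = field(default_factory=ReadConfig)
    rnaseq: RnaSeqConfig = field(default_factory=RnaSeqConfig)

    def validate(self) -> None:
        if self.reads.fragment_min >= self.reads.fragment_max:
            raise SimulationError("fragment range: min must be < max")
        for name, value in [
            ("background_length", self.background_length),
            ("tile_length", self.tile_length),
            ("n_control_tiles", self.n_control_tiles),
        ]:
            if value <= 0:
                raise SimulationError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# domain containers


@dataclass(frozen=True)
class ElementRecord:
    """An SVA-like element with its annotated internal regions."""

    element_id: str
    chrom: str
    start: int
    end: int
    subfamily: str
    sequence: str
    #: region name -> (start, end), genome coordinates, 0-based half-open
    regions: Mapping[str, tuple]

    @property
    def length(self) -> int:
        return self.end - self.start

    def subgenome_entry(self):
        return (self.element_id, self.sequence, self.chrom, self.start, self.end)


@dataclass
class GroundTruth:
    """Planted truth for the downstream acceptance checks."""

    repeat_classes: dict
    element_occupied: dict
    motif_consensus: str
    motif_placements: list
    affinity_a: np.ndarray | None = None
    affinity_b: np.ndarray | None = None
    expression: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "repeat_classes": self.repeat_classes,
            "element_occupied": self.element_occupied,
            "motif_consensus": self.motif_consensus,
            "motif_placements": self.motif_placements,
        }
        if self.expression is not None:
            payload["expression"] = self.expression.to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SyntheticGenome:
    config: SimConfig
    sequence: str
    repeats: list
    elements: list
    truth: GroundTruth

    @property
    def length(self) -> int:
        return len(self.sequence)

    def repeats_by_id(self) -> dict:
        return {r.repeat_id: r for r in self.repeats}

    def elements_by_id(self) -> dict:
        return {e.element_id: e for e in self.elements}

    def repeat_bed(self) -> pd.DataFrame:
        rows = [
            (r.chrom, r.start, r.end, r.repeat_id, self.truth.repeat_classes[r.repeat_id], "+", r.family)
            for r in self.repeats
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand", "family"])

    def element_bed(self) -> pd.DataFrame:
        rows = []
        for e in self.elements:
            regions = ";".join(f"{k}:{s}-{t}" for k, (s, t) in e.regions.items())
            rows.append((e.chrom, e.start, e.end, e.element_id, 0, "+", e.subfamily, regions))
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand", "subfamily", "regions"]
        )


class FastqRead(NamedTuple):
    name: str
    sequence: str
    quality: str


# ---------------------------------------------------------------------------
# genome generation


def _make_tr(rng, mix: RepeatMix, planted: bool) -> tuple[str, str, list[int]]:
    """One tandem repeat: (unit, full sequence, per-copy site offsets)."""
    if planted:
        pad = random_seq(rng, mix.unit_length - len(mix.consensus), gc=0.5)
        copies = []
        offsets = []
        for i in range(mix.units):
            site = mutate(rng, mix.consensus, mix.site_mutation_rate)
            copies.append(site + pad)
            offsets.append(i * mix.unit_length)
        unit = mix.consensus + pad
        return unit, "".join(copies), offsets
    unit = random_seq(rng, mix.unit_length, gc=0.5)
    return unit, unit * mix.units, []


def _make_sva(rng, cfg: SvaConfig, consensus: str, canonical: dict) -> tuple[str, dict, int]:
    """One SVA-like element; returns (sequence, relative regions, vntr copies)."""
    copies = int(rng.integers(cfg.vntr_copies_min, cfg.vntr_copies_max + 1))
    hexamer = "CCCTCT" * cfg.hexamer_copies
    vntr = canonical["vntr_unit"] * copies
    parts = [hexamer, canonical["alu"], vntr, canonical["siner"], "A" * cfg.polya_length]
    names = ["hexamer", "alu_like", "vntr", "sine_r", "polya"]
    regions = {}
    pos = 0
    for name, part in zip(names, parts):
        regions[name] = (pos, pos + len(part))
        pos += len(part)
    seq = mutate(rng, "".join(parts), cfg.divergence)
    return seq, regions, copies


def generate_repeat_genome(config: SimConfig) -> SyntheticGenome:
    """Build the synthetic genome, annotations and ground truth.

    Raises a sizing error when ``background_length`` cannot host the
    requested features with at least ``min_spacer`` background between them.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mix, sva_cfg, alpha = config.repeats, config.sva, config.alphoid

    # canonical SVA internals, shared by the family, diverged per element
    canonical = {
        "alu": random_seq(rng, sva_cfg.alu_length, gc=0.55),
        # VNTR unit: two juxtaposed copies of the planted site plus a GC-rich pad
        "vntr_unit": mix.consensus + mix.consensus + random_seq(rng, sva_cfg.vntr_pad, gc=0.85),
        "siner": random_seq(rng, sva_cfg.siner_length, gc=0.5),
    }
    alphoid_unit = random_seq(rng, alpha.unit_length, gc=0.45)

    features = []  # (kind, seq, meta)
    classes = (
        ["CO_BOUND"] * mix.n_cobound
        + ["A_ONLY"] * mix.n_a_only
        + ["B_ONLY"] * mix.n_b_only
        + ["NONE"] * mix.n_background
    )
    rng.shuffle(classes)
    placements_local: list = []
    for i, cls in enumerate(classes):
        planted = cls != "NONE"
        unit, seq, offsets = _make_tr(rng, mix, planted)
        features.append(("TR", seq, {"unit": unit, "class": cls, "offsets": offsets}))

    sva_names = [p[0] for p in sva_cfg.subfamily_props]
    sva_probs = np.array([p[1] for p in sva_cfg.subfamily_props], float)
    sva_probs /= sva_probs.sum()
    n_occ = int(round(sva_cfg.n_elements * sva_cfg.occupied_fraction))
    occupied_flags = np.array([True] * n_occ + [False] * (sva_cfg.n_elements - n_occ))
    rng.shuffle(occupied_flags)
    for i in range(sva_cfg.n_elements):
        seq, regions, copies = _make_sva(rng, sva_cfg, mix.consensus, canonical)
        sub = sva_names[int(rng.choice(len(sva_names), p=sva_probs))]
        features.append(
            ("SVA", seq, {"regions": regions, "subfamily": sub, "occupied": bool(occupied_flags[i])})
        )

    for i in range(alpha.n_arrays):
        with_box = rng.random() < alpha.cenpb_fraction
        units = []
        for _ in range(alpha.units):
            u = mutate(rng, alphoid_unit, alpha.divergence)
            if with_box:
                off = alpha.cenpb_offset
                u = u[:off] + CENPB_BOX_LIKE + u[off + len(CENPB_BOX_LIKE) :]
            units.append(u)
        features.append(("ALPHOID", "".join(units), {"with_box": with_box}))

    feature_len = sum(len(seq) for _, seq, _ in features)
    n_gaps = len(features) + 1
    spacer = config.background_length // n_gaps
    if spacer < config.min_spacer:
        deficit = config.min_spacer * n_gaps - config.background_length
        raise SimulationError(
            f"background_length too small to host {len(features)} features: "
            f"need at least {config.min_spacer * n_gaps} background bases "
            f"({deficit} more than configured)"
        )

    parts: list[str] = []
    pos = 0
    repeats: list[RepeatRecord] = []
    elements: list[ElementRecord] = []
    repeat_classes: dict = {}
    element_occupied: dict = {}
    placements: list = []
    n_tr = 0
    n_alpha = 0
    for kind, seq, meta in features:
        bg = random_seq(rng, spacer, gc=config.gc)
        parts.append(bg)
        pos += len(bg)
        start, end = pos, pos + len(seq)
        if kind == "TR":
            rid = f"TR{n_tr:05d}"
            n_tr += 1
            repeats.append(
                RepeatRecord(
                    repeat_id=rid,
                    chrom=CHROM,
                    start=start,
                    end=end,
                    unit_length=len(meta["unit"]),
                    copy_number=len(seq) / len(meta["unit"]),
                    unit_sequence=meta["unit"],
                    full_sequence=seq,
                    family="TR_SIMPLE",
                )
            )
            repeat_classes[rid] = meta["class"]
            placements.extend((rid, off) for off in meta["offsets"])
        elif kind == "SVA":
            eid = f"SVA{len(elements):05d}"
            regions = {k: (start + s, start + t) for k, (s, t) in meta["regions"].items()}
            elements.append(
                ElementRecord(
                    element_id=eid,
                    chrom=CHROM,
                    start=start,
                    end=end,
                    subfamily=meta["subfamily"],
                    sequence=seq,
                    regions=regions,
                )
            )
            element_occupied[eid] = meta["occupied"]
        else:
            rid = f"ALPHA{n_alpha:05d}"
            n_alpha += 1
            repeats.append(
                RepeatRecord(
                    repeat_id=rid,
                    chrom=CHROM,
                    start=start,
                    end=end,
                    unit_length=alpha.unit_length,
                    copy_number=alpha.units,
                    unit_sequence=seq[: alpha.unit_length],
                    full_sequence=seq,
                    family="ALPHOID",
                )
            )
            repeat_classes[rid] = alpha.planted_class
        parts.append(seq)
        pos = end
    tail = config.background_length - spacer * len(features)
    parts.append(random_seq(rng, tail, gc=config.gc))

    sequence = "".join(parts)
    truth = GroundTruth(
        repeat_classes=repeat_classes,
        element_occupied=element_occupied,
        motif_consensus=mix.consensus,
        motif_placements=placements,
    )
    genome = SyntheticGenome(
        config=config, sequence=sequence, repeats=repeats, elements=elements, truth=truth
    )
    truth.affinity_a, truth.affinity_b = simulate_occupancy(genome, config)
    return genome


def simulate_occupancy(genome: SyntheticGenome, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-base linear affinity tracks for proteins A and B.

    Co-bound repeats are enriched for both proteins, single-protein repeats
    enriched for one and depleted for the other, background uniform at the
    background level.  Occupied SVA-like elements concentrate protein-B
    affinity on their VNTR interval.
    """
    lv = config.occupancy
    g = len(genome.sequence)
    track_a = np.full(g, lv.background, dtype=np.float64)
    track_b = np.full(g, lv.background, dtype=np.float64)
    for rec in genome.repeats:
        cls = genome.truth.repeat_classes[rec.repeat_id]
        if cls == "NONE":
            continue
        sl = slice(rec.start, rec.end)
        if cls == "CO_BOUND":
            track_a[sl] = lv.enriched
            track_b[sl] = lv.enriched
        elif cls == "A_ONLY":
            track_a[sl] = lv.enriched
            track_b[sl] = lv.depleted
        elif cls == "B_ONLY":
            track_a[sl] = lv.depleted
            track_b[sl] = lv.enriched
    for el in genome.elements:
        if genome.truth.element_occupied[el.element_id]:
            s, t = el.regions["vntr"]
            track_b[s:t] = config.sva.vntr_affinity
    return track_a, track_b


# ---------------------------------------------------------------------------
# array simulation


def build_tiles(genome: SyntheticGenome, config: SimConfig | None = None) -> list[Tile]:
    """Repeat tiles plus random-sequence control tiles."""
    config = config or genome.config
    tiles = tile_catalogue(genome.repeats, config.tile_length)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    for i in range(config.n_control_tiles):
        tiles.append(
            Tile(
                tile_id=f"CTRL{i:05d}",
                repeat_id=None,
                offset=0,
                sequence=random_seq(rng, config.tile_length, gc=0.5),
                is_control=True,
            )
        )
    return tiles


def _tile_affinity(genome: SyntheticGenome, tiles: Sequence[Tile], track: np.ndarray,
                   background: float) -> np.ndarray:
    by_id = genome.repeats_by_id()
    out = np.empty(len(tiles))
    for i, t in enumerate(tiles):
        if t.is_control or t.repeat_id is None:
            out[i] = background
        else:
            rec = by_id[t.repeat_id]
            s = rec.start + t.offset
            out[i] = track[s : s + len(t.sequence)].mean()
    return out / background


def simulate_array(
    genome: SyntheticGenome,
    tiles: Sequence[Tile],
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Raw two-channel intensities per tile/protein/replicate (long format).

    Channel 2 (input) is proportional to the tile's hybridization copy
    factor; channel 1 (ChIP) additionally carries the affinity ratio, the
    shared per-tile trend, and the dye-bias curve.  ``fold_expect`` is the
    noise-free expected linear enrichment of each row.
    """
    if not tiles:
        raise SimulationError("no tiles supplied")
    config = config or genome.config
    arr = config.array
    rng = rng if rng is not None else np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n = len(tiles)
    copy_factor = arr.base_intensity * 2 ** rng.normal(0.0, arr.copy_log2_sd, n)
    trend = rng.normal(0.0, arr.trend_log2_sd, n)
    c1, c2, c3 = arr.dye_bias
    a_center = np.log2(copy_factor).mean()

    aff = {
        "A": _tile_affinity(genome, tiles, genome.truth.affinity_a, config.occupancy.background),
        "B": _tile_affinity(genome, tiles, genome.truth.affinity_b, config.occupancy.background),
    }
    tile_ids = [t.tile_id for t in tiles]
    is_control = [t.is_control for t in tiles]
    frames = []
    for protein in ("A", "B"):
        # dye bias is a smooth function of the feature's expected mean
        # log-intensity A, so the lowess fit of M against A can remove it
        m_expect = np.log2(aff[protein]) + trend
        a_expect = np.log2(copy_factor) + 0.5 * m_expect
        x = a_expect - a_center
        dye = c1 * x + c2 * x**2 + c3 * x**3
        for rep in range(1, arr.replicates + 1):
            g1 = 2 ** rng.normal(0.0, arr.channel_log2_sd)
            g2 = 2 ** rng.normal(0.0, arr.channel_log2_sd)
            noise1 = 2 ** rng.normal(0.0, arr.noise_log2_sd, n)
            noise2 = 2 ** rng.normal(0.0, arr.noise_log2_sd, n)
            ch2 = g2 * copy_factor * noise2
            ch1 = g1 * copy_factor * aff[protein] * 2 ** (trend + dye) * noise1
            frames.append(
                pd.DataFrame(
                    {
                        "tile_id": tile_ids,
                        "is_control": is_control,
                        "protein": protein,
                        "replicate": rep,
                        "ch1": ch1,
                        "ch2": ch2,
                        "fold_expect": aff[protein],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    sequence: str,
    track: np.ndarray | None,
    n_reads: int,
    mode: str,
    config: ReadConfig | None = None,
    rng: np.random.Generator | None = None,
    prefix: str = "read",
) -> list[FastqRead]:
    """Single-end reads from sonicated fragments.

    ChIP mode samples the protein-bound position proportionally to the
    affinity track and places a fragment covering it uniformly; input mode
    samples fragment positions uniformly.  One read of ``read_length`` bases
    is taken from a uniformly chosen fragment end/strand.
    """
    if n_reads <= 0:
        raise SimulationError("n_reads must be > 0")
    if mode not in ("chip", "input"):
        raise SimulationError(f"unknown mode {mode!r}")
    config = config or ReadConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    g = len(sequence)
    rl = config.read_length
    if g < config.fragment_max:
        raise SimulationError("reference shorter than the maximum fragment")
    if mode == "chip":
        if track is None:
            raise SimulationError("chip mode requires an affinity track")
        p = np.asarray(track, dtype=np.float64)
        p = p / p.sum()
        sites = rng.choice(g, size=n_reads, p=p)
    else:
        sites = rng.integers(0, g, size=n_reads)
    flen = rng.integers(config.fragment_min, config.fragment_max + 1, size=n_reads)
    offset = rng.integers(0, flen)
    fstart = np.clip(sites - offset, 0, g - flen)
    strand = rng.integers(0, 2, size=n_reads)
    errors = None
    if config.error_rate > 0:
        errors = rng.random((n_reads, rl)) < config.error_rate
        subs = rng.integers(1, 4, size=(n_reads, rl))
    reads = []
    qual = "I" * rl
    for i in range(n_reads):
        fs = int(fstart[i])
        fe = fs + int(flen[i])
        if strand[i] == 0:
            seq = sequence[fs : fs + rl]
        else:
            seq = revcomp(sequence[fe - rl : fe])
        if errors is not None and errors[i].any():
            codes = encode(seq).copy()
            hit = errors[i]
            codes[hit] = (codes[hit] + subs[i][hit]) % 4
            seq = decode(codes)
        reads.append(FastqRead(f"{prefix}:{mode}:{i}", seq, qual))
    return reads


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path) -> list[FastqRead]:
    reads = []
    with open(path) as fh:
        while True:
            name = fh.readline().strip()
            if not name:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            reads.append(FastqRead(name[1:], seq, qual))
    return reads


# ---------------------------------------------------------------------------
# RNA-seq counts


@dataclass
class RnaSeqSim:
    counts: pd.DataFrame          # raw counts, elements x libraries
    libraries: pd.DataFrame       # library, condition, total_reads, is_reference
    elements: pd.DataFrame        # element_id, subfamily
    truth: pd.DataFrame           # element_id, state, base_mean, fold_<condition>


def simulate_rnaseq_counts(
    cfg: RnaSeqConfig,
    rng: np.random.Generator | None = None,
    elements: pd.DataFrame | None = None,
    subfamily_props: tuple = SvaConfig.subfamily_props,
) -> RnaSeqSim:
    """Raw element count tables across conditions plus planted fold truth.

    Per-condition log2 fold effects of silent elements are
    ``mu_c + sd * (sqrt(rho) z + sqrt(1-rho) u)`` with a latent ``z`` shared
    by the conditions in ``latent_group``, giving pairwise correlation
    ``rho`` of planted log-folds; ``mu_c`` is set so the linear-scale mean
    equals the condition's ``mean_fold``.  Expressed elements keep fold 1.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if not any(c.is_reference for c in cfg.conditions):
        raise SimulationError("no reference condition configured")
    if cfg.library_total <= 0 or cfg.denominator <= 0:
        raise SimulationError("library_total and denominator must be positive")
    n = cfg.n_elements
    if elements is None:
        names = [p[0] for p in subfamily_props]
        probs = np.array([p[1] for p in subfamily_props], float)
        probs /= probs.sum()
        subs = [names[int(k)] for k in rng.choice(len(names), size=n, p=probs)]
        elements = pd.DataFrame(
            {"element_id": [f"SVA{i:05d}" for i in range(n)], "subfamily": subs}
        )
    else:
        n = len(elements)

    silent = rng.random(n) < cfg.silent_fraction
    base = np.where(
        silent,
        rng.uniform(*cfg.silent_base_range, size=n),
        rng.uniform(*cfg.expressed_base_range, size=n),
    )
    sd = cfg.log2_fold_sd
    rho = cfg.latent_corr
    z = rng.normal(size=n)
    folds = {}
    for cond in cfg.conditions:
        if cond.is_reference:
            folds[cond.name] = np.ones(n)
            continue
        mu = np.log2(cond.mean_fold) - sd**2 * np.log(2) / 2.0
        u = rng.normal(size=n)
        if cond.name in cfg.latent_group:
            lam = mu + sd * (np.sqrt(rho) * z + np.sqrt(1 - rho) * u)
        else:
            lam = mu + sd * u
        f = 2.0**lam
        f[~silent] = 1.0  # already-expressed elements do not respond
        folds[cond.name] = f

    scale = cfg.library_total / cfg.denominator
    counts = {}
    lib_rows = []
    for cond in cfg.conditions:
        for k in range(1, cfg.n_libraries + 1):
            lib = f"{cond.name}_{k}"
            lam = base * folds[cond.name] * scale
            counts[lib] = rng.poisson(lam)
            lib_rows.append((lib, cond.name, cfg.library_total, cond.is_reference))
    counts_df = pd.DataFrame(counts, index=elements["element_id"].to_numpy())
    counts_df.index.name = "element_id"
    libraries = pd.DataFrame(lib_rows, columns=["library", "condition", "total_reads", "is_reference"])
    truth = pd.DataFrame(
        {
            "element_id": elements["element_id"].to_numpy(),
            "subfamily": elements["subfamily"].to_numpy(),
            "state": np.where(silent, "silent", "expressed"),
            "base_mean": base,
            **{f"fold_{name}": f for name, f in folds.items()},
        }
    )
    return RnaSeqSim(counts=counts_df, libraries=libraries, elements=elements, truth=truth)


# ---------------------------------------------------------------------------
# direct differential matrix (for the moderated-statistic analyses)


def simulate_sam_matrix(
    rng: np.random.Generator,
    n_tiles: int = 5000,
    reps: tuple = (3, 3),
    frac_shifted: float = 0.1,
    effect_sd: float = 4.0,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two replicate groups with a planted mean shift in a tile fraction.

    Returns (group A matrix, group B matrix, boolean shifted mask); the
    shift is ``effect_sd`` times the per-replicate noise sd, added to group B.
    """
    ka, kb = reps
    m_a = rng.normal(0.0, noise_sd, size=(n_tiles, ka))
    m_b = rng.normal(0.0, noise_sd, size=(n_tiles, kb))
    shifted = np.zeros(n_tiles, dtype=bool)
    n_shift = int(round(frac_shifted * n_tiles))
    idx = rng.choice(n_tiles, size=n_shift, replace=False)
    shifted[idx] = True
    m_b[shifted] += effect_sd * noise_sd
    return m_a, m_b, shifted
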
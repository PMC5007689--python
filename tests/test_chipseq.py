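"""Aligner contract (vs exhaustive scan), enrichment, validation, profiles."""
import numpy as np
import pandas as pd
import pytest

from repeatbind import catalog, chipseq, simulate
from repeatbind.catalog import Tile
from repeatbind.chipchip import OccupancyCall
from repeatbind.chipseq import (
    AlignmentError,
    align_reads,
    metaprofile,
    occupancy_fraction,
    profile_matrix,
    quantify_tiles,
    validate_calls,
)
from repeatbind.dnautil import encode, random_seq, revcomp
from repeatbind.simulate import FastqRead


def brute_force_align(reads, refs, budget):
    """All-positions mismatch scan, best stratum, deterministic tie-break."""
    order = {r: i for i, r in enumerate(sorted(refs))}
    rows = []
    for read in reads:
        best = None
        length = len(read.sequence)
        for strand_rank, s in enumerate((read.sequence, revcomp(read.sequence))):
            arr = encode(s)
            for rid, refseq in refs.items():
                ref = encode(refseq)
                if len(ref) < length:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(ref, length)
                mm = (windows != arr[None, :]).sum(axis=1)
                for pos in np.nonzero(mm <= budget)[0]:
                    key = (int(mm[pos]), order[rid], int(pos), strand_rank)
                    if best is None or key < best[:4]:
                        best = key + (rid,)
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
    return pd.DataFrame(rows, columns=chipseq.HIT_COLUMNS)


def mutate_at(seq, positions):
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


class TestAligner:
    def test_exact_copy_hits_source_position(self, rng):
        ref = random_seq(rng, 3000, gc=0.5)
        read = FastqRead("r0", ref[1234:1284], "I" * 50)
        hits = align_reads([read], {"ref": ref}, max_mismatches=0)
        row = hits.iloc[0]
        assert (row.ref_id, row.pos, row.strand, row.mismatches) == ("ref", 1234, "+", 0)

    def test_identity_threshold_boundary(self, rng):
        ref = random_seq(rng, 2000, gc=0.5)
        core = ref[500:550]
        two = FastqRead("two", mutate_at(core, [3, 27]), "I" * 50)
        three = FastqRead("three", mutate_at(core, [3, 27, 44]), "I" * 50)
        hits = align_reads([two, three], {"ref": ref}, min_identity=0.95)
        assert list(hits["read_id"]) == ["two"]  # 47/50 = 0.94 identity rejected
        assert hits.iloc[0]["mismatches"] == 2

    def test_minus_strand_reads_are_found(self, rng):
        ref = random_seq(rng, 1000, gc=0.5)
        read = FastqRead("rc", revcomp(ref[200:250]), "I" * 50)
        hits = align_reads([read], {"ref": ref}, max_mismatches=0)
        assert (hits.iloc[0]["pos"], hits.iloc[0]["strand"]) == (200, "-")

    def test_matches_exhaustive_scan_on_repeat_subgenome(self, small_genome, rng):
        refs_all, _ = catalog.build_subgenome(
            [r.subgenome_entry() for r in small_genome.repeats]
        )
        # ~10 kb of tandem-repeat references: the worst case for tie-breaking
        refs = {}
        total = 0
        for rid, seq in refs_all.items():
            refs[rid] = seq
            total += len(seq)
            if total > 10_000:
                break
        concat = "".join(refs.values())
        reads = []
        for i in range(200):
            start = int(rng.integers(0, len(concat) - 50))
            seq = concat[start : start + 50]
            n_mut = int(rng.integers(0, 4))
            seq = mutate_at(seq, list(rng.choice(50, size=n_mut, replace=False)))
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(FastqRead(f"r{i}", seq, "I" * 50))
        mine = align_reads(reads, refs, max_mismatches=2)
        oracle = brute_force_align(reads, refs, budget=2)
        pd.testing.assert_frame_equal(
            mine.reset_index(drop=True), oracle.reset_index(drop=True)
        )

    def test_empty_subgenome_rejected(self):
        with pytest.raises(AlignmentError):
            align_reads([], {}, max_mismatches=0)

    def test_exactly_one_threshold_kind_allowed(self, rng):
        ref = random_seq(rng, 500, gc=0.5)
        read = FastqRead("r", ref[:50], "I")
        with pytest.raises(AlignmentError):
            align_reads([read], {"ref": ref}, max_mismatches=0, min_identity=0.95)


# ---------------------------------------------------------------------------
# quantification


def hits_frame(entries):
    return pd.DataFrame(entries, columns=["read_id", "ref_id", "pos", "strand", "mismatches", "identity"])


class TestQuantifyTiles:
    def tile(self):
        return [Tile("R|t0", "R", 0, "A" * 50)]

    def test_count_ratio_with_equal_totals(self):
        chip = hits_frame([(f"c{i}", "R", 0, "+", 0, 1.0) for i in range(20)])
        inp = hits_frame([(f"i{i}", "R", 0, "+", 0, 1.0) for i in range(10)])
        out = quantify_tiles(chip, inp, self.tile(), total_chip=100, total_input=100,
                             pseudocount=0.0)
        assert np.isclose(out.iloc[0]["ratio"], 2.0)

    def test_density_invariant_to_library_scaling(self):
        chip = hits_frame([(f"c{i}", "R", 0, "+", 0, 1.0) for i in range(20)])
        inp = hits_frame([(f"i{i}", "R", 0, "+", 0, 1.0) for i in range(10)])
        a = quantify_tiles(chip, inp, self.tile(), total_chip=1000, total_input=1000)
        doubled = pd.concat([chip, chip.assign(read_id=chip["read_id"] + "x")])
        b = quantify_tiles(doubled, inp, self.tile(), total_chip=2000, total_input=1000)
        assert np.isclose(a.iloc[0]["chip_density"], b.iloc[0]["chip_density"])

    def test_empty_hit_sets_rejected(self):
        chip = hits_frame([("c", "R", 0, "+", 0, 1.0)])
        with pytest.raises(AlignmentError):
            quantify_tiles(chip, hits_frame([]), self.tile())


# ---------------------------------------------------------------------------
# the cross-platform validation rule


def call(rid, cls):
    return OccupancyCall(rid, cls, f"{rid}|t0", (), (), 0.0, 0.0)


def enrichment_tables(ratios_by_protein):
    """ratios_by_protein: protein -> list per replicate of {tile: ratio}."""
    out = {}
    for protein, reps in ratios_by_protein.items():
        tables = []
        for rep in reps:
            rows = [(tid, tid.split("|")[0], 0, 0, 0.0, 0.0, ratio) for tid, ratio in rep.items()]
            tables.append(
                pd.DataFrame(
                    rows,
                    columns=["tile_id", "repeat_id", "chip_count", "input_count",
                             "chip_density", "input_density", "ratio"],
                )
            )
        out[protein] = tables
    return out


class TestValidationRule:
    CASES = [
        # (class, ratios per protein per replicate for the repeat's tile, expected)
        ("A_ONLY", {"A": [2.5, 2.1], "B": [0.5, 0.5]}, True),
        ("A_ONLY", {"A": [2.5, 1.4], "B": [0.5, 0.5]}, False),
        ("A_ONLY", {"A": [2.0, 2.0], "B": [0.5, 0.5]}, True),   # boundary inclusive
        ("B_ONLY", {"A": [0.5, 0.5], "B": [3.0, 2.2]}, True),
        ("B_ONLY", {"A": [9.0, 9.0], "B": [1.9, 5.0]}, False),
        ("CO_BOUND", {"A": [2.5, 2.5], "B": [2.5, 2.5]}, True),
        ("CO_BOUND", {"A": [2.5, 2.5], "B": [2.5, 1.5]}, False),  # B fails one rep
        ("CO_BOUND", {"A": [1.0, 1.0], "B": [5.0, 5.0]}, False),  # A fails entirely
    ]

    @pytest.mark.parametrize("cls, ratios, expected", CASES)
    def test_truth_table(self, cls, ratios, expected):
        tables = enrichment_tables(
            {p: [{"R|t0": r} for r in reps] for p, reps in ratios.items()}
        )
        (validated,) = validate_calls([call("R", cls)], tables)
        assert validated.validated is expected

    def test_any_tile_may_carry_the_validation(self):
        tables = enrichment_tables(
            {
                "A": [{"R|t0": 0.5, "R|t50": 2.5}, {"R|t0": 0.4, "R|t50": 2.1}],
                "B": [{"R|t0": 0.5, "R|t50": 0.5}, {"R|t0": 0.5, "R|t50": 0.5}],
            }
        )
        (validated,) = validate_calls([call("R", "A_ONLY")], tables)
        assert validated.validated is True

    def test_reproducibility_is_per_tile_not_per_repeat(self):
        # different tiles passing in different replicates do not validate
        tables = enrichment_tables(
            {
                "A": [{"R|t0": 2.5, "R|t50": 0.5}, {"R|t0": 0.5, "R|t50": 2.5}],
                "B": [{"R|t0": 0.5, "R|t50": 0.5}, {"R|t0": 0.5, "R|t50": 0.5}],
            }
        )
        (validated,) = validate_calls([call("R", "A_ONLY")], tables)
        assert validated.validated is False

    def test_unclassified_repeats_are_not_flagged(self):
        tables = enrichment_tables({"A": [{"R|t0": 5.0}], "B": [{"R|t0": 5.0}]})
        (out,) = validate_calls([call("R", "UNCLASSIFIED")], tables)
        assert out.validated is None

    def test_raising_min_fold_never_validates_more(self):
        tables = enrichment_tables(
            {"A": [{"R|t0": 2.5}, {"R|t0": 2.2}], "B": [{"R|t0": 0.5}, {"R|t0": 0.5}]}
        )
        low = validate_calls([call("R", "A_ONLY")], tables, min_fold=2.0)[0].validated
        high = validate_calls([call("R", "A_ONLY")], tables, min_fold=2.4)[0].validated
        assert low is True and high is False

    def test_missing_protein_data_is_an_error(self):
        tables = enrichment_tables({"A": [{"R|t0": 2.5}]})
        with pytest.raises(AlignmentError, match="B"):
            validate_calls([call("R", "CO_BOUND")], tables)


# ---------------------------------------------------------------------------
# profiles and the occupied fraction


class TestMetaprofile:
    def test_uniform_hits_give_a_flat_profile(self, rng):
        n = 50_000
        pos = rng.integers(0, 4950, size=n)
        hits = hits_frame([(f"r{i}", "E", int(p), "+", 0, 1.0) for i, p in enumerate(pos)])
        prof = metaprofile(hits, [("E", 0, 5000)], bin_width=50, read_length=50)
        # read centers start at pos + 25, so the two edge bins see half mass
        density = prof["density"].to_numpy()[1:-1]
        assert density.max() / density.min() < 1.5

    def test_empty_hits_give_all_zero_profile(self):
        prof = metaprofile(hits_frame([]), [("E", 0, 500)], bin_width=50)
        assert (prof["density"] == 0).all()

    def test_raw_bins_conserve_assigned_read_centers(self, rng):
        pos = rng.integers(0, 450, size=1000)
        hits = hits_frame([(f"r{i}", "E", int(p), "+", 0, 1.0) for i, p in enumerate(pos)])
        prof = metaprofile(hits, [("E", 0, 500)], bin_width=50, read_length=50)
        centers = pos + 25
        assert prof["raw_count"].sum() == (centers < 500).sum()

    def test_element_shorter_than_bin_rejected(self):
        with pytest.raises(AlignmentError):
            metaprofile(hits_frame([]), [("E", 0, 30)], bin_width=50)


class TestOccupancyFraction:
    def test_all_zero_profiles_give_zero_fraction(self):
        frac, labels, _ = occupancy_fraction(np.zeros((20, 10)), np.zeros(20), k=4)
        assert frac == 0.0

    def test_fraction_invariant_under_element_permutation(self, rng):
        profiles = np.vstack(
            [rng.normal(10, 1, size=(30, 10)), rng.normal(0.5, 0.1, size=(20, 10))]
        )
        enr = np.concatenate([np.full(30, 3.0), np.full(20, 0.8)])
        frac1, _, _ = occupancy_fraction(profiles, enr, k=4, seed=1)
        perm = rng.permutation(50)
        frac2, _, _ = occupancy_fraction(profiles[perm], enr[perm], k=4, seed=1)
        assert np.isclose(frac1, frac2)
        assert np.isclose(frac1, 0.6)

    def test_k_below_two_rejected(self):
        with pytest.raises(AlignmentError):
            occupancy_fraction(np.zeros((10, 5)), np.zeros(10), k=1)
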
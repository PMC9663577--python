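"""Subgenome homology classification against rules and a per-base oracle."""

import numpy as np
import pytest

from polytereg.core import AlignmentBlock, GenomicInterval
from polytereg.homology import (
    class_fractions,
    classify_regions,
    locate_by_majority_overlap,
    locate_in_classes,
)

SIZES = {"1A": 10_000, "1B": 10_000, "1D": 10_000}


def _block(qc, qs, qe, sc, ss, se):
    return AlignmentBlock(
        GenomicInterval(qc, qs, qe), GenomicInterval(sc, ss, se), 95.0
    )


def _sym_blocks(pairs):
    """Build the six directed lists from symmetric (cA, s, e, cB) tuples."""
    blocks = {(x, y): [] for x in "ABD" for y in "ABD" if x != y}
    for cx, s, e, cy in pairs:
        x, y = cx[-1], cy[-1]
        blocks[(x, y)].append(_block(cx, s, e, cy, s, e))
        blocks[(y, x)].append(_block(cy, s, e, cx, s, e))
    return blocks


class TestClassifyRegions:
    def test_reciprocal_run_in_both_partners_is_homo3(self):
        blocks = _sym_blocks([
            ("1A", 1000, 1500, "1B"),
            ("1A", 1000, 1500, "1D"),
        ])
        classes = classify_regions(blocks, [], SIZES)
        homo3_a = [c for c in classes
                   if c.klass == "homo3" and c.interval.chrom == "1A"]
        assert [(c.interval.start, c.interval.end) for c in homo3_a] == [(1000, 1500)]

    def test_short_runs_fall_below_threshold(self):
        blocks = _sym_blocks([("1A", 1000, 1300, "1B"), ("1A", 1000, 1300, "1D")])
        classes = classify_regions(blocks, [], SIZES)
        a = [c for c in classes if c.interval.chrom == "1A" and c.klass != "homoeo3"]
        assert all(c.klass == "specific" for c in a)

    def test_single_partner_is_homo2(self):
        blocks = _sym_blocks([("1A", 2000, 3000, "1B")])
        classes = classify_regions(blocks, [], SIZES)
        homo2_a = [c for c in classes
                   if c.klass == "homo2" and c.interval.chrom == "1A"]
        assert [(c.interval.start, c.interval.end) for c in homo2_a] == [(2000, 3000)]

    def test_syntenic_homo3_also_homoeo3(self):
        blocks = _sym_blocks([("1A", 1000, 2000, "1B"), ("1A", 1000, 2000, "1D")])
        syn = [GenomicInterval("1A", 0, 5000)]
        classes = classify_regions(blocks, syn, SIZES)
        kinds = {c.klass for c in classes if c.interval.chrom == "1A"
                 and c.interval.start == 1000}
        assert kinds == {"homo3", "homoeo3"}

    def test_missing_direction_is_error(self):
        blocks = _sym_blocks([("1A", 1000, 2000, "1B")])
        del blocks[("B", "A")]
        with pytest.raises(ValueError, match=r"\(B, A\)"):
            classify_regions(blocks, [], SIZES)

    def test_non_reciprocal_alignment_ignored(self):
        # forward A->B exists but B->A maps elsewhere: not reciprocal
        blocks = {(x, y): [] for x in "ABD" for y in "ABD" if x != y}
        blocks[("A", "B")].append(_block("1A", 1000, 2000, "1B", 1000, 2000))
        blocks[("B", "A")].append(_block("1B", 5000, 6000, "1A", 5000, 6000))
        classes = classify_regions(blocks, [], SIZES)
        a = [c for c in classes if c.interval.chrom == "1A" and c.klass != "homoeo3"]
        assert all(c.klass == "specific" for c in a)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_mosaic_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(50):
            x, y = rng.choice(["1A", "1B", "1D"], size=2, replace=False)
            s = int(rng.integers(0, 9000))
            e = int(rng.integers(s + 100, min(10_000, s + 1500)))
            pairs.append((x, s, e, y))
        blocks = _sym_blocks(pairs)
        classes = classify_regions(blocks, [], SIZES, min_len=400)

        # independent per-base oracle
        for chrom in SIZES:
            sg = chrom[-1]
            others = [o for o in "ABD" if o != sg]
            count = np.zeros(SIZES[chrom], dtype=int)
            for other in others:
                mask = np.zeros(SIZES[chrom], dtype=bool)
                for cx, s, e, cy in pairs:
                    if cx == chrom and cy[-1] == other:
                        mask[s:e] = True
                    if cy == chrom and cx[-1] == other:
                        mask[s:e] = True
                # enforce the > 400 bp run rule brute-force
                run = 0
                for i in range(SIZES[chrom] + 1):
                    inside = i < SIZES[chrom] and mask[i]
                    if inside:
                        run += 1
                    else:
                        if 0 < run <= 400:
                            mask[i - run : i] = False
                        run = 0
                count += mask
            expected = np.where(count == 2, 2, np.where(count == 1, 1, 0))
            got = np.full(SIZES[chrom], -1, dtype=int)
            code = {"specific": 0, "homo2": 1, "homo3": 2}
            for c in classes:
                if c.interval.chrom == chrom and c.klass != "homoeo3":
                    got[c.interval.start : c.interval.end] = code[c.klass]
            assert (got == expected).all()

    def test_fractions_sum_to_one(self):
        blocks = _sym_blocks([
            ("1A", 1000, 2000, "1B"), ("1A", 1500, 2600, "1D"),
            ("1B", 4000, 6000, "1D"),
        ])
        classes = classify_regions(blocks, [GenomicInterval("1A", 0, 10_000)], SIZES)
        fr = class_fractions(classes, SIZES)
        assert fr[["specific", "homo2", "homo3"]].sum() == pytest.approx(1.0)

    def test_subgenome_relabeling_preserves_class_counts(self):
        pairs = [("1A", 1000, 2000, "1B"), ("1A", 3000, 4000, "1D"),
                 ("1B", 5000, 7000, "1D"), ("1A", 5000, 5600, "1B")]
        swap = {"1A": "1B", "1B": "1A", "1D": "1D"}
        swapped = [(swap[a], s, e, swap[b]) for a, s, e, b in pairs]
        f1 = class_fractions(classify_regions(_sym_blocks(pairs), [], SIZES), SIZES)
        f2 = class_fractions(classify_regions(_sym_blocks(swapped), [], SIZES), SIZES)
        assert f1["specific"] == f2["specific"]
        assert f1["homo2"] == f2["homo2"]
        assert f1["homo3"] == f2["homo3"]


class TestLocate:
    def _classes(self):
        blocks = _sym_blocks([("1A", 2000, 4000, "1B"), ("1A", 2000, 4000, "1D")])
        return classify_regions(blocks, [], SIZES)

    def test_midpoint_rule(self):
        classes = self._classes()
        labels, summary = locate_in_classes(
            [GenomicInterval("1A", 2500, 2600)], classes
        )
        assert labels == ["homo3"]
        # straddling query labelled by midpoint
        labels, _ = locate_in_classes([GenomicInterval("1A", 1900, 2060)], classes)
        assert labels == ["specific"]
        labels, _ = locate_in_classes([GenomicInterval("1A", 1950, 2110)], classes)
        assert labels == ["homo3"]

    def test_majority_overlap_alternative(self):
        classes = self._classes()
        labels = locate_by_majority_overlap(
            [GenomicInterval("1A", 1900, 2060)], classes
        )
        assert labels == ["specific"]  # 100 bp specific vs 60 bp homo3

    def test_empty_query_gives_empty_summary(self):
        labels, summary = locate_in_classes([], self._classes())
        assert labels == [] and summary == {}

    def test_unknown_chromosome_is_error(self):
        with pytest.raises(ValueError):
            locate_in_classes([GenomicInterval("9Z", 0, 10)], self._classes())

    def test_fractions_sum_to_one(self):
        classes = self._classes()
        rng = np.random.default_rng(2)
        queries = [
            GenomicInterval("1A", int(s), int(s) + 100)
            for s in rng.integers(0, 9900, 200)
        ]
        _, summary = locate_in_classes(queries, classes)
        assert sum(summary.values()) == pytest.approx(1.0)
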
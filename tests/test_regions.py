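"""Region grouping/extension, top-k retention and similarity summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genescout.errors import StageError
from genescout.regions import (
    CandidateRegion,
    PipelineConfig,
    group_and_extend,
    region_similarity_summary,
    retain_top_queries,
)
from genescout.seeding import Hsp


def _hsp(gene="g", contig="c", strand="+", start=0, end=100, bits=50.0,
         isoform="i1", pident=90.0, cov=0.5):
    return Hsp(
        gene_id=gene, isoform_id=isoform, contig=contig, strand=strand,
        start=start, end=end, pident=pident, aln_len=(end - start) // 3,
        query_cov=cov, evalue=1e-9, bits=bits,
    )


CONFIG = PipelineConfig()
LENGTHS = {"c": 200_000}


class TestGroupAndExtend:
    def test_merge_within_gap_and_clip_at_zero(self):
        hsps = [_hsp(start=10_000, end=12_000), _hsp(start=100_000, end=105_000)]
        (region,) = group_and_extend(hsps, CONFIG, LENGTHS)
        assert (region.start, region.end) == (0, 115_000)
        assert len(region.member_hsps) == 2

    def test_gap_at_or_above_threshold_splits(self):
        hsps = [_hsp(start=10_000, end=12_000), _hsp(start=115_000, end=120_000)]
        regions = group_and_extend(hsps, CONFIG, LENGTHS)
        assert len(regions) == 2

    def test_strand_specific_grouping(self):
        hsps = [_hsp(strand="+", start=5000, end=6000),
                _hsp(strand="-", start=5000, end=6000)]
        regions = group_and_extend(hsps, CONFIG, LENGTHS)
        assert len(regions) == 2
        assert {r.strand for r in regions} == {"+", "-"}

    def test_unknown_contig_rejected(self):
        with pytest.raises(StageError, match="unknown contig"):
            group_and_extend([_hsp(contig="nope")], CONFIG, LENGTHS)

    def test_clip_at_contig_end(self):
        hsps = [_hsp(start=195_000, end=199_000)]
        (region,) = group_and_extend(hsps, CONFIG, LENGTHS)
        assert region.end == 200_000


def _oracle_components(hsps, merge_gap):
    """Brute-force connected components of the interval graph with edges
    between same-(gene,contig,strand) HSPs at gap < merge_gap."""
    n = len(hsps)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = hsps[i], hsps[j]
            if (a.gene_id, a.contig, a.strand) != (b.gene_id, b.contig, b.strand):
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap < merge_gap:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(hsps[i])
    return {
        frozenset((h.start, h.end, h.isoform_id) for h in members)
        for members in comps.values()
    }


def _random_hsp_set(rng, n):
    return [
        _hsp(
            gene=f"g{rng.integers(1, 4)}",
            strand="+-"[rng.integers(0, 2)],
            start=(s := int(rng.integers(0, 180_000))),
            end=s + int(rng.integers(100, 9000)),
            isoform=f"i{k}",
        )
        for k, s_ in enumerate(range(n))
    ]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_groups_match_connected_components(self, seed):
        rng = np.random.default_rng(seed)
        hsps = _random_hsp_set(rng, int(rng.integers(1, 60)))
        config = PipelineConfig(merge_gap=int(rng.integers(1000, 50_000)))
        regions = group_and_extend(hsps, config, LENGTHS)
        mine = {
            frozenset((h.start, h.end, h.isoform_id) for h in r.member_hsps)
            for r in regions
        }
        assert mine == _oracle_components(hsps, config.merge_gap)

    @pytest.mark.parametrize("seed", range(10))
    def test_merge_gap_monotonicity(self, seed):
        rng = np.random.default_rng(100 + seed)
        hsps = _random_hsp_set(rng, 40)
        counts = [
            len(group_and_extend(hsps, PipelineConfig(merge_gap=g), LENGTHS))
            for g in (1000, 10_000, 100_000, 1_000_000)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_every_hsp_in_exactly_one_region(self):
        rng = np.random.default_rng(5)
        hsps = _random_hsp_set(rng, 50)
        regions = group_and_extend(hsps, CONFIG, LENGTHS)
        placed = [h for r in regions for h in r.member_hsps]
        assert len(placed) == len(hsps)
        assert {id(h) for h in placed} == {id(h) for h in hsps}


class TestRetainTopQueries:
    def _region(self, hsps):
        return CandidateRegion(
            region_id="R1", gene_id="g", contig="c", strand="+",
            start=0, end=10_000, member_hsps=hsps,
        )

    def test_top_five_at_identical_location(self):
        hsps = [
            _hsp(start=100, end=400, bits=90 - 10 * k, isoform=f"i{k}")
            for k in range(7)
        ]
        region = retain_top_queries(self._region(hsps), top_k=5)
        assert len(region.member_hsps) == 5
        assert {h.isoform_id for h in region.member_hsps} == {f"i{k}" for k in range(5)}

    def test_distinct_locations_all_kept(self):
        hsps = [
            _hsp(start=100 * k, end=100 * k + 50, isoform=f"i{k}") for k in range(6)
        ]
        region = retain_top_queries(self._region(hsps), top_k=5)
        assert len(region.member_hsps) == 6

    def test_tie_broken_by_isoform_id(self):
        hsps = [
            _hsp(start=0, end=300, bits=b, isoform=i)
            for b, i in [(90, "i1"), (80, "i2"), (70, "i3"), (60, "i4"),
                         (50, "i5"), (50, "i6")]
        ]
        region = retain_top_queries(self._region(hsps), top_k=5)
        kept = {h.isoform_id for h in region.member_hsps}
        assert "i5" in kept and "i6" not in kept


class TestSimilaritySummary:
    def _region(self, members):
        return CandidateRegion(
            region_id="R1", gene_id="g", contig="c", strand="+",
            start=0, end=1000,
            member_hsps=[_hsp(pident=p, cov=c) for p, c in members],
        )

    @pytest.mark.parametrize(
        "members, expected",
        [
            ([(88.0, 0.6), (95.5, 0.9)], (95.5, 0.9)),
            ([(100.0, 1.0)], (100.0, 1.0)),
            ([(90.0, 0.5), (80.0, 0.95)], (90.0, 0.95)),
        ],
    )
    def test_maxima_taken_independently(self, members, expected):
        assert region_similarity_summary(self._region(members)) == expected

    def test_empty_region_is_error(self):
        region = self._region([])
        with pytest.raises(StageError):
            region_similarity_summary(region)


@given(
    starts=st.lists(st.integers(0, 150_000), min_size=1, max_size=30),
    merge_gap=st.integers(1, 120_000),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_region_intervals_contain_members(starts, merge_gap):
    hsps = [_hsp(start=s, end=s + 500) for s in starts]
    regions = group_and_extend(
        hsps, PipelineConfig(merge_gap=merge_gap), LENGTHS
    )
    for r in regions:
        for h in r.member_hsps:
            assert r.start <= h.start and h.end <= r.end
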
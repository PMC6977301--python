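"""Benchmark curation: pair derivation, negatives, variants, matched subsets."""

import io

import numpy as np
import pytest

from egbench.annotations import (
    GenomicInterval,
    interval_point_gap,
    window_distance,
)
from egbench.curation import (
    CandidatePair,
    CurationPolicy,
    curate_dataset,
    fixed_ratio_variant,
    generate_negatives,
    matched_subsets,
    negative_cutoff,
    pairs_from_associations,
    pairs_from_links,
    read_benchmark_tsv,
    strip_ambiguous,
    write_benchmark_tsv,
)
from egbench.interaction_io import ChromatinLink, VariantGeneAssociation, read_chiapet
from egbench.simulate import SimulationConfig, simulate_annotation, simulate_links

from conftest import make_element, make_tss


def link(c, s1, e1, s2, e2, assay="chiapet", support=5.0):
    return ChromatinLink(
        GenomicInterval(c, s1, e1), GenomicInterval(c, s2, e2), support, assay
    )


def pair(eid, gid, label="positive", dist=5000, ambiguous=False, chrom="chr1",
         start=0, end=100):
    return CandidatePair(
        element_id=eid, gene_id=gid, label=label, ambiguous=ambiguous,
        distance=dist, chrom=chrom, element_start=start, element_end=end,
    )


def brute_force_link_pairs(links, elements, tss, window=2000):
    """Exhaustive enumeration over (link, orientation, element, gene)."""
    support = {}
    for ln in links:
        for ea, ta in [(ln.anchor1, ln.anchor2), (ln.anchor2, ln.anchor1)]:
            hit = [el for el in elements if el.interval.overlaps(ea)]
            genes = sorted(
                {
                    s.gene_id
                    for s in tss
                    if s.chrom == ta.chrom
                    and window_distance(ta.start, ta.end, s.pos) <= window
                }
            )
            if not hit or not genes:
                continue
            amb = len(genes) >= 2
            for el in hit:
                for g in genes:
                    key = (el.element_id, g)
                    support[key] = support.get(key, False) or not amb
    return {(e, g, not unamb) for (e, g), unamb in support.items()}


class TestPairsFromLinks:
    TSS = make_tss(("GA", "chr1", 50_000), ("GB", "chr1", 52_000),
                   ("GC", "chr1", 120_000))
    EL = [make_element("E1", "chr1", 10_000, 10_300)]

    def test_multi_gene_anchor_flags_all_pairs_ambiguous(self):
        links = [link("chr1", 10_000, 10_300, 50_500, 51_000)]
        positives, amb = pairs_from_links(links, self.EL, self.TSS)
        assert {(p.gene_id, p.ambiguous) for p in positives} == {
            ("GA", True),
            ("GB", True),
        }
        assert amb == {"E1": {"GA", "GB"}}

    def test_anchor_without_promoter_window_tss_yields_no_pair(self):
        links = [link("chr1", 10_000, 10_300, 80_000, 80_500)]
        positives, _ = pairs_from_links(links, self.EL, self.TSS)
        assert positives == []

    def test_unambiguous_support_clears_the_flag(self):
        links = [
            link("chr1", 10_000, 10_300, 50_500, 51_000),  # reaches GA and GB
            link("chr1", 10_000, 10_300, 47_500, 48_500),  # reaches GA only
        ]
        positives, amb = pairs_from_links(links, self.EL, self.TSS)
        flags = {p.gene_id: p.ambiguous for p in positives}
        assert flags == {"GA": False, "GB": True}
        assert amb == {"E1": {"GB"}}

    def test_matches_bruteforce_enumeration_on_toy_genome(self, annotation, evidence):
        links = read_chiapet(io.StringIO(evidence.chiapet))
        positives, _ = pairs_from_links(links, annotation.elements, annotation.tss)
        got = {(p.element_id, p.gene_id, p.ambiguous) for p in positives}
        expected = brute_force_link_pairs(links, annotation.elements, annotation.tss)
        assert got == expected


class TestPairsFromAssociations:
    def test_containment_produces_the_positive(self):
        tss = make_tss(("G", "chr1", 50_000))
        el = make_element("E1", "chr1", 10_000, 10_300)
        result = pairs_from_associations(
            [VariantGeneAssociation("chr1", 10_100, "G")], [el], tss
        )
        assert [(p.element_id, p.gene_id) for p in result] == [("E1", "G")]

    def test_variant_outside_every_element_yields_nothing(self):
        tss = make_tss(("G", "chr1", 50_000))
        el = make_element("E1", "chr1", 10_000, 10_300)
        result = pairs_from_associations(
            [VariantGeneAssociation("chr1", 20_000, "G")], [el], tss
        )
        assert list(result) == []

    def test_unknown_gene_is_skipped_and_counted(self):
        tss = make_tss(("G", "chr1", 50_000))
        el = make_element("E1", "chr1", 10_000, 10_300)
        result = pairs_from_associations(
            [VariantGeneAssociation("chr1", 10_100, "NOPE")], [el], tss
        )
        assert list(result) == [] and result.n_skipped == 1

    def test_matches_bruteforce_containment_scan(self):
        rng = np.random.default_rng(17)
        tss = make_tss(*[(f"G{i}", "chr1", int(p)) for i, p in
                         enumerate(rng.integers(0, 200_000, size=10))])
        elements = [make_element(f"E{i}", "chr1", int(s), int(s) + 300)
                    for i, s in enumerate(range(0, 200_000, 4_000))]
        assocs = [
            VariantGeneAssociation("chr1", int(rng.integers(0, 200_000)), f"G{rng.integers(10)}")
            for _ in range(50)
        ]
        got = {(p.element_id, p.gene_id)
               for p in pairs_from_associations(assocs, elements, tss)}
        expected = {
            (el.element_id, a.gene_id)
            for a in assocs
            for el in elements
            if el.interval.contains(a.pos)
        }
        assert got == expected


class TestNegativeCutoff:
    def test_nearest_rank_on_1_to_20(self):
        positives = [pair("E", f"G{d}", dist=d) for d in range(1, 21)]
        assert negative_cutoff(positives, percentile=95) == 19

    def test_single_positive_degenerate_percentile(self):
        assert negative_cutoff([pair("E", "G", dist=777)]) == 777

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        dists = rng.integers(1, 10_000, size=37)
        base = [pair("E", f"G{i}", dist=int(d)) for i, d in enumerate(dists)]
        shuffled = [base[i] for i in rng.permutation(len(base))]
        assert negative_cutoff(base) == negative_cutoff(shuffled)

    def test_empty_positives_error(self):
        with pytest.raises(ValueError):
            negative_cutoff([])


class TestGenerateNegatives:
    TSS = make_tss(("GA", "chr1", 30_000), ("GB", "chr1", 40_000),
                   ("GC", "chr1", 200_000))
    EL = [make_element("E1", "chr1", 10_000, 10_300)]

    def positives(self):
        return [pair("E1", "GA", dist=19_700, chrom="chr1", start=10_000, end=10_300)]

    def test_positive_gene_never_becomes_negative(self):
        negs = generate_negatives(self.positives(), {}, self.EL, self.TSS, 50_000)
        assert {n.gene_id for n in negs} == {"GB"}

    def test_gene_just_past_cutoff_is_excluded(self):
        # GB sits 29700 bases from E1; a cutoff one base short excludes it
        negs = generate_negatives(self.positives(), {}, self.EL, self.TSS, 29_699)
        assert negs == []
        negs = generate_negatives(self.positives(), {}, self.EL, self.TSS, 29_700)
        assert {n.gene_id for n in negs} == {"GB"}

    def test_ambiguous_genes_excluded_when_requested(self):
        negs = generate_negatives(
            self.positives(), {"E1": {"GB"}}, self.EL, self.TSS, 50_000,
            exclude_ambiguous=True,
        )
        assert negs == []

    def test_element_with_only_far_positives_spawns_no_negatives(self):
        far = [pair("E1", "GC", dist=189_700, chrom="chr1", start=10_000, end=10_300)]
        assert generate_negatives(far, {}, self.EL, self.TSS, 50_000) == []

    def test_matches_bruteforce_scan_on_toy_genome(self, annotation, evidence):
        links = read_chiapet(io.StringIO(evidence.chiapet))
        positives, amb = pairs_from_links(links, annotation.elements, annotation.tss)
        cutoff = negative_cutoff(positives)
        negs = generate_negatives(
            positives, amb, annotation.elements, annotation.tss, cutoff
        )
        pos_keys = {(p.element_id, p.gene_id) for p in positives}
        eligible = {
            p.element_id for p in positives if p.distance <= cutoff
        }
        expected = set()
        for el in annotation.elements:
            if el.element_id not in eligible:
                continue
            for g in annotation.tss.genes():
                iv = el.interval
                gaps = [
                    interval_point_gap(iv.start, iv.end, s.pos)
                    for s in annotation.tss.gene_sites(g)
                    if s.chrom == iv.chrom
                ]
                if gaps and min(gaps) <= cutoff and (el.element_id, g) not in pos_keys:
                    expected.add((el.element_id, g))
        assert {(n.element_id, n.gene_id) for n in negs} == expected


def curated_toy_dataset(seed=7, bidirectional_rate=0.4):
    config = SimulationConfig(seed=seed, bidirectional_rate=bidirectional_rate)
    annotation = simulate_annotation(config)
    evidence = simulate_links(annotation, config)
    links = read_chiapet(io.StringIO(evidence.chiapet))
    positives, amb = pairs_from_links(links, annotation.elements, annotation.tss)
    return curate_dataset(
        "toy-chiapet", "chiapet", "simB", positives, amb,
        annotation.elements, annotation.tss,
    )


class TestDatasetVariants:
    def test_no_pair_carries_both_labels(self):
        ds = curated_toy_dataset()
        pos = {p.key for p in ds.positives()}
        neg = {p.key for p in ds.negatives()}
        assert not pos & neg

    def test_every_negative_within_cutoff(self):
        ds = curated_toy_dataset()
        assert all(n.distance <= ds.cutoff for n in ds.negatives())

    def test_strip_ambiguous_removes_flagged_pairs_and_their_genes(self):
        ds = curated_toy_dataset()
        assert any(p.ambiguous for p in ds.positives()), "fixture lacks ambiguity"
        stripped = strip_ambiguous(ds)
        assert not any(p.ambiguous for p in stripped.positives())
        for eid, genes in ds.ambiguous_genes.items():
            kept = {n.gene_id for n in stripped.negatives() if n.element_id == eid}
            assert not kept & genes

    def test_strip_ambiguous_noop_without_ambiguity(self):
        ds = curated_toy_dataset()
        clean = strip_ambiguous(ds)
        again = strip_ambiguous(clean)
        assert {p.key for p in again.pairs} == {p.key for p in clean.pairs}

    def test_strip_ambiguous_warns_for_explicit_gene_assays(self):
        ds = curated_toy_dataset()
        ds.assay = "eqtl"
        with pytest.warns(UserWarning, match="no-op"):
            out = strip_ambiguous(ds)
        assert out is ds

    def test_fixed_ratio_respects_min_negative_rule(self):
        policy = CurationPolicy(rng_seed=1)
        tss = make_tss(*[(f"G{i}", "chr1", 30_000 + 5_000 * i) for i in range(12)])
        el = make_element("E1", "chr1", 10_000, 10_300)
        pos = [pair("E1", "G0", dist=19_700, start=10_000, end=10_300)]
        from egbench.curation import BenchmarkDataset

        # 3 eligible negatives -> element excluded entirely
        few = [pair("E1", f"G{i}", label="negative", dist=20_000 + i,
                    start=10_000, end=10_300) for i in (1, 2, 3)]
        ds = BenchmarkDataset("d", "chiapet", "b", "all_natural", pos + few, policy)
        assert fixed_ratio_variant(ds).pairs == []

        # 10 eligible negatives, 1 positive -> exactly 4 retained negatives
        many = [pair("E1", f"G{i}", label="negative", dist=20_000 + i,
                     start=10_000, end=10_300) for i in range(1, 11)]
        ds = BenchmarkDataset("d", "chiapet", "b", "all_natural", pos + many, policy)
        fixed = fixed_ratio_variant(ds)
        assert len(fixed.positives()) == 1 and len(fixed.negatives()) == 4

    def test_fixed_ratio_excludes_cross_dataset_positive_genes(self):
        policy = CurationPolicy(rng_seed=1)
        pos = [pair("E1", "G0", dist=19_700)]
        negs = [pair("E1", f"G{i}", label="negative", dist=20_000 + i)
                for i in range(1, 7)]
        from egbench.curation import BenchmarkDataset

        ds = BenchmarkDataset("d", "chiapet", "b", "all_natural", pos + negs, policy)
        fixed = fixed_ratio_variant(ds, cross_dataset_positives={"E1": {"G1", "G2"}})
        kept = {n.gene_id for n in fixed.negatives()}
        assert not kept & {"G1", "G2"}

    def test_fixed_ratio_same_seed_reproducible_and_positives_seed_invariant(self):
        ds1 = curated_toy_dataset()
        fixed_a = fixed_ratio_variant(ds1)
        fixed_b = fixed_ratio_variant(curated_toy_dataset())
        assert fixed_a.pairs == fixed_b.pairs
        import dataclasses

        ds2 = dataclasses.replace(
            curated_toy_dataset(), policy=CurationPolicy(rng_seed=99)
        )
        fixed_c = fixed_ratio_variant(ds2)
        assert {p.key for p in fixed_c.positives()} == {
            p.key for p in fixed_a.positives()
        }

    def test_strip_then_fixed_preserves_disjoint_labels_and_ratio(self):
        ds = fixed_ratio_variant(strip_ambiguous(curated_toy_dataset()))
        pos = {p.key for p in ds.positives()}
        neg = {p.key for p in ds.negatives()}
        assert not pos & neg
        by_el = {}
        for p in ds.pairs:
            by_el.setdefault(p.element_id, [0, 0])[0 if p.label == "positive" else 1] += 1
        for np_, nn in by_el.values():
            assert nn <= ds.policy.fixed_ratio * np_


class TestMatchedSubsets:
    def test_ratio_mode_enforces_global_ratio(self):
        ds = curated_toy_dataset()
        sub = matched_subsets(ds, "ratio")
        assert len(sub.negatives()) == ds.policy.matched_ratio * len(sub.positives())

    def test_promoter_mode_drops_genes_without_both_labels(self):
        ds = curated_toy_dataset()
        sub = matched_subsets(ds, "promoter")
        pos_genes = {p.gene_id for p in ds.positives()}
        neg_genes = {n.gene_id for n in ds.negatives()}
        allowed = pos_genes & neg_genes
        assert {p.gene_id for p in sub.pairs} <= allowed

    def test_distance_mode_balances_bins(self):
        ds = curated_toy_dataset()
        sub = matched_subsets(ds, "distance")
        assert sub.positives(), "distance matching produced no pairs"
        import numpy as np

        from egbench.curation import _quantile_bin_edges

        edges = _quantile_bin_edges(
            np.array([p.distance for p in ds.positives()], dtype=float),
            ds.policy.n_distance_bins,
        )
        counts = np.histogram([p.distance for p in sub.positives()],
                              bins=np.nan_to_num(edges, posinf=1e18, neginf=-1e18))[0]
        occupied = counts[counts > 0]
        assert occupied.max() - occupied.min() <= 1

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            matched_subsets(curated_toy_dataset(), "nope")


def test_benchmark_tsv_round_trip(tmp_path):
    ds = curated_toy_dataset()
    path = tmp_path / "bench.tsv"
    write_benchmark_tsv(ds, path)
    back = read_benchmark_tsv(path)
    assert [(p.key, p.label, p.distance, p.ambiguous) for p in back.pairs] == [
        (p.key, p.label, p.distance, p.ambiguous) for p in ds.pairs
    ]
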
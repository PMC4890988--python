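"""Genotype-side statistics: QC, HWE, trend test, mapping, LD, tagging, min-p."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import pathfuse as pf
from pathfuse.datatypes import (
    GenotypeDataset,
    GeneAnnotation,
    QCThresholds,
    ReferencePanel,
)
from pathfuse.errors import (
    ConsistencyError,
    EmptyAfterQCError,
    MonomorphicSNPError,
    ParseError,
    UndefinedStatisticError,
)
from pathfuse.genotypes import (
    cochran_armitage_trend,
    gene_wise_association,
    hwe_test,
    map_snps_to_genes,
    pairwise_r2,
    select_tag_snps,
    snp_qc,
    trend_test_all,
)


def make_dataset(calls, phenotypes, positions=None, chrom="1"):
    calls = np.asarray(calls, dtype=np.int8)
    n_snps = calls.shape[1]
    positions = positions or [1000 * (j + 1) for j in range(n_snps)]
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(n_snps)],
            "chrom": chrom,
            "pos": positions,
            "allele_minor": "A",
            "allele_major": "G",
        }
    )
    return GenotypeDataset(
        sample_ids=[f"i{k}" for k in range(calls.shape[0])],
        phenotypes=np.asarray(phenotypes, dtype=np.int8),
        snps=snps,
        calls=calls,
    )


class TestHWE:
    def test_exact_hwe_proportions_give_p_one(self):
        p, mono = hwe_test((25, 50, 25))
        assert p == pytest.approx(1.0)
        assert not mono

    def test_worked_chisq_example(self):
        # hand formula: p_hat=0.5, expected (25,50,25), chi2 = 4.0, df=1
        p, mono = hwe_test((30, 40, 30))
        assert p == pytest.approx(stats.chi2.sf(4.0, 1), rel=1e-12)
        assert p == pytest.approx(0.0455, abs=5e-4)
        assert not mono

    def test_monomorphic_flagged(self):
        p, mono = hwe_test((50, 0, 0))
        assert p == 1.0 and mono

    def test_exact_option_matches_enumeration(self):
        # tiny counts: enumerate P(het | allele counts) by hand
        p, _ = hwe_test((3, 2, 3), method="exact")
        assert 0 < p <= 1
        # equilibrium-looking counts should not be extreme under the exact test
        p2, _ = hwe_test((25, 50, 25), method="exact")
        assert p2 > 0.5

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_test((0, 0, 0))
        with pytest.raises(ValueError):
            hwe_test((-1, 2, 3))


class TestTrend:
    def test_identical_distributions_null(self):
        stat, p = cochran_armitage_trend((10, 20, 10), (10, 20, 10))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_worked_example(self):
        stat, p = cochran_armitage_trend((10, 15, 25), (20, 15, 15))
        assert stat == pytest.approx(5.797, abs=1e-3)
        assert p == pytest.approx(0.0160, abs=1e-3)

    def test_doubling_counts_sharpens(self):
        s1, p1 = cochran_armitage_trend((10, 15, 25), (20, 15, 15))
        s2, p2 = cochran_armitage_trend((20, 30, 50), (40, 30, 30))
        assert s2 > s1 and p2 < p1

    def test_degenerate_single_class(self):
        with pytest.raises(UndefinedStatisticError):
            cochran_armitage_trend((10, 0, 0), (20, 0, 0))

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.integers(0, 60), min_size=6, max_size=6))
    def test_matches_direct_formula(self, counts):
        r, s = np.array(counts[:3], float), np.array(counts[3:], float)
        if r.sum() == 0 or s.sum() == 0:
            return
        w = np.array([0.0, 1.0, 2.0])
        n = r + s
        N, R = n.sum(), r.sum()
        num = N * (r @ w) - R * (n @ w)
        den = R * (N - R) * (N * (n @ w**2) - (n @ w) ** 2)
        if den <= 0:
            with pytest.raises(UndefinedStatisticError):
                cochran_armitage_trend(tuple(counts[:3]), tuple(counts[3:]))
            return
        expect = N * num**2 / den
        stat, p = cochran_armitage_trend(tuple(counts[:3]), tuple(counts[3:]))
        assert stat == pytest.approx(expect, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(expect, 1), rel=1e-12)

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, size=(120, 15)).astype(np.int8)
        phen = np.array([1] * 60 + [0] * 60)
        ds = make_dataset(calls, phen)
        out = trend_test_all(ds)
        for j in range(15):
            col = calls[:, j]
            rc = tuple(int(((col == g) & (phen == 1)).sum()) for g in (0, 1, 2))
            sc = tuple(int(((col == g) & (phen == 0)).sum()) for g in (0, 1, 2))
            stat, p = cochran_armitage_trend(rc, sc)
            assert out["statistic"][j] == pytest.approx(stat, rel=1e-12)
            assert out["p"][j] == pytest.approx(p, rel=1e-12)


class TestQC:
    def test_constructed_failures_each_filter(self):
        rng = np.random.default_rng(0)
        n = 200
        phen = np.array([1] * 100 + [0] * 100)
        # SNP0: MAF ~0.005; SNP1: gross HWE violation; SNP2: call rate 0.1;
        # SNP3, SNP4: clean, MAF 0.3
        col0 = np.zeros(n, np.int8); col0[:2] = 1
        col1 = np.array([0, 2] * 100, np.int8)  # no hets at p=0.5
        col2 = np.full(n, -1, np.int8); col2[:20] = rng.integers(0, 3, 20)
        clean = (rng.random((n, 2)) < 0.3).astype(np.int8) + (
            rng.random((n, 2)) < 0.3
        ).astype(np.int8)
        calls = np.column_stack([col0, col1, col2, clean])
        ds = make_dataset(calls, phen)
        kept, report = snp_qc(ds, QCThresholds())
        assert kept.n_snps == 2
        t = report.table
        assert "low_maf" in t.loc[t.snp_id == "s0", "reasons"].iloc[0]
        assert "hwe_fail" in t.loc[t.snp_id == "s1", "reasons"].iloc[0]
        assert "low_call_rate" in t.loc[t.snp_id == "s2", "reasons"].iloc[0]
        assert report.n_passed == 2 and report.n_removed == 3

    def test_zero_thresholds_keep_everything(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(50, 10)).astype(np.int8)
        ds = make_dataset(calls, [1] * 25 + [0] * 25)
        kept, report = snp_qc(ds, QCThresholds(0.0, 0.0, 0.0))
        assert kept.n_snps == 10 and report.n_removed == 0

    def test_random_fixture_matches_direct_recount(self):
        # oracle: recompute the three statistics independently per SNP
        rng = np.random.default_rng(2)
        n, m = 300, 200
        phen = np.array([1] * 150 + [0] * 150)
        maf = rng.uniform(0.002, 0.4, m)
        calls = (rng.random((n, m)) < maf).astype(np.int8) + (
            rng.random((n, m)) < maf
        ).astype(np.int8)
        calls[rng.random((n, m)) < 0.02] = -1
        ds = make_dataset(calls, phen)
        thr = QCThresholds(maf_min=0.01, hwe_p_min=0.001, call_rate_min=0.95)
        kept, report = snp_qc(ds, thr)
        survivors = 0
        controls = calls[150:]
        for j in range(m):
            col = calls[:, j]
            obs = col[col >= 0]
            cr = len(obs) / n
            af = obs.sum() / (2 * len(obs)) if len(obs) else np.nan
            mafj = min(af, 1 - af)
            cc = controls[:, j]; cc = cc[cc >= 0]
            counts = tuple(int((cc == g).sum()) for g in (0, 1, 2))
            hp = pf.hwe_test(counts)[0] if sum(counts) else 1.0
            if cr >= 0.95 and mafj >= 0.01 and hp >= 0.001:
                survivors += 1
        assert kept.n_snps == survivors

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        calls = (rng.random((200, 50)) < 0.3).astype(np.int8) + (
            rng.random((200, 50)) < 0.3
        ).astype(np.int8)
        ds = make_dataset(calls, [1] * 100 + [0] * 100)
        once, _ = snp_qc(ds)
        twice, rep = snp_qc(once)
        assert twice.n_snps == once.n_snps and rep.n_removed == 0

    def test_empty_after_qc_raises(self):
        calls = np.zeros((40, 2), np.int8)  # monomorphic: MAF 0 everywhere
        ds = make_dataset(calls, [1] * 20 + [0] * 20)
        with pytest.raises(EmptyAfterQCError):
            snp_qc(ds)


class TestMapping:
    def ann(self):
        return GeneAnnotation(
            table=pd.DataFrame(
                {
                    "gene_id": ["A", "B"],
                    "chrom": ["1", "1"],
                    "start": [100_000, 160_000],
                    "end": [105_000, 170_000],
                }
            )
        )

    def snps(self, positions, chrom="1"):
        return pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(len(positions))],
                "chrom": chrom,
                "pos": positions,
                "allele_minor": "A",
                "allele_major": "G",
            }
        )

    def test_window_boundary_inclusive(self):
        asn = map_snps_to_genes(self.snps([50_000, 49_999]), self.ann())
        assert asn.genes_for("s0") == ["A"]
        assert asn.unmapped == ["s1"]

    def test_gene_body_mapped(self):
        asn = map_snps_to_genes(self.snps([102_000]), self.ann())
        assert asn.genes_for("s0") == ["A"]

    def test_overlapping_windows_map_to_both(self):
        # 130,000 is within 50kb of A's end (105,000) and B's start (160,000)
        asn = map_snps_to_genes(self.snps([130_000]), self.ann())
        assert set(asn.genes_for("s0")) == {"A", "B"}

    def test_chromosome_name_clash_raises(self):
        with pytest.raises(ParseError, match="chr1"):
            map_snps_to_genes(self.snps([102_000], chrom="chr1"), self.ann())


def panel_from_haplotypes(hap, ids=None):
    hap = np.asarray(hap, dtype=np.int8)
    ids = ids or [f"s{j}" for j in range(hap.shape[1])]
    return ReferencePanel(snp_ids=ids, haplotypes=hap, phased=True)


class TestPairwiseR2:
    def test_self_r2_is_one(self):
        rng = np.random.default_rng(0)
        panel = panel_from_haplotypes((rng.random((100, 2)) < 0.3).astype(int))
        assert pairwise_r2(panel, "s0", "s0") == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        # haplotype counts AB=25, Ab=25, aB=25, ab=25
        hap = np.array([[1, 1]] * 25 + [[1, 0]] * 25 + [[0, 1]] * 25 + [[0, 0]] * 25)
        assert pairwise_r2(panel_from_haplotypes(hap), "s0", "s1") == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        # AB=40, Ab=10, aB=10, ab=40 -> D=0.15, r2 = D^2/(pA pa pB pb) = 0.36
        hap = np.array([[1, 1]] * 40 + [[1, 0]] * 10 + [[0, 1]] * 10 + [[0, 0]] * 40)
        assert pairwise_r2(panel_from_haplotypes(hap), "s0", "s1") == pytest.approx(0.36, rel=1e-12)

    def test_monomorphic_raises(self):
        hap = np.column_stack([np.ones(50, int), np.random.default_rng(0).integers(0, 2, 50)])
        with pytest.raises(MonomorphicSNPError):
            pairwise_r2(panel_from_haplotypes(hap), "s0", "s1")


def greedy_cover_is_valid(tagset, panel, gene_snp_ids, thr):
    tags = set(tagset.tags)
    for s in gene_snp_ids:
        if s in tags:
            continue
        tag, r2 = tagset.coverage[s]
        assert tag in tags
        assert pairwise_r2(panel, s, tag) >= thr


def exhaustive_min_cover(panel, ids, thr):
    """Smallest subset of ids covering all ids at r2 >= thr (oracle)."""
    m = len(ids)
    cov = np.zeros((m, m), bool)
    for a in range(m):
        for b in range(m):
            try:
                cov[a, b] = pairwise_r2(panel, ids[a], ids[b]) >= thr
            except MonomorphicSNPError:
                cov[a, b] = a == b
    for k in range(1, m + 1):
        for subset in itertools.combinations(range(m), k):
            if np.any(cov[list(subset)], axis=0).all():
                return k
    return m


class TestTagSelection:
    def test_single_snp_is_own_tag(self):
        rng = np.random.default_rng(0)
        panel = panel_from_haplotypes((rng.random((100, 1)) < 0.3).astype(int))
        ts = select_tag_snps("g", ["s0"], panel)
        assert ts.tags == ["s0"]

    def test_hub_covers_two_spokes(self):
        # a correlates strongly with b and c; b,c weakly with each other
        rng = np.random.default_rng(1)
        a = (rng.random(2000) < 0.5).astype(int)
        flip = rng.random(2000) < 0.02
        b = np.where(flip, 1 - a, a)
        flip2 = rng.random(2000) < 0.02
        c = np.where(flip2, 1 - a, a)
        panel = panel_from_haplotypes(np.column_stack([b, a, c]), ["b", "a", "c"])
        assert pairwise_r2(panel, "a", "b") > 0.8
        assert pairwise_r2(panel, "a", "c") > 0.8
        ts = select_tag_snps("g", ["a", "b", "c"], panel,
                             positions={"a": 10, "b": 20, "c": 30})
        assert ts.tags == ["a"]
        greedy_cover_is_valid(ts, panel, ["a", "b", "c"], 0.8)

    def test_full_redundancy_one_tag(self):
        col = (np.random.default_rng(2).random(200) < 0.4).astype(int)
        panel = panel_from_haplotypes(np.column_stack([col, col, col]))
        ts = select_tag_snps("g", ["s0", "s1", "s2"], panel)
        assert len(ts.tags) == 1

    def test_absent_and_monomorphic_are_own_tags(self):
        rng = np.random.default_rng(3)
        hap = np.column_stack([
            (rng.random(100) < 0.3).astype(int), np.zeros(100, int)
        ])
        panel = panel_from_haplotypes(hap)
        ts = select_tag_snps("g", ["s0", "s1", "notinpanel"], panel)
        assert set(ts.tags) >= {"s1", "notinpanel"}
        assert ts.n_tags == 3

    def test_empty_gene_raises(self):
        panel = panel_from_haplotypes(np.zeros((10, 1), int))
        with pytest.raises(ValueError):
            select_tag_snps("g", [], panel)

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_valid_and_near_minimal(self, seed):
        # random LD structures with <=8 SNPs: cover must be valid (exact),
        # and greedy size <= exhaustive minimum + 1
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 9))
        base = (rng.random(400) < rng.uniform(0.2, 0.5)).astype(int)
        cols = []
        for _ in range(m):
            if rng.random() < 0.5:
                flip = rng.random(400) < rng.uniform(0.0, 0.3)
                cols.append(np.where(flip, 1 - base, base))
            else:
                cols.append((rng.random(400) < rng.uniform(0.2, 0.5)).astype(int))
        panel = panel_from_haplotypes(np.column_stack(cols))
        ids = [f"s{j}" for j in range(m)]
        ts = select_tag_snps("g", ids, panel, 0.8)
        greedy_cover_is_valid(ts, panel, ids, 0.8)
        assert ts.n_tags <= exhaustive_min_cover(panel, ids, 0.8) + 1


class TestGeneWiseAssociation:
    def asn(self, pairs):
        from pathfuse.datatypes import SNPGeneAssignment

        return SNPGeneAssignment(
            pairs=pd.DataFrame(pairs, columns=["snp_id", "gene_id"]),
            unmapped=[],
            window_bp=50_000,
        )

    def tagset(self, gene, tags):
        from pathfuse.datatypes import TagSet

        return TagSet(gene_id=gene, tags=tags, coverage={}, r2_threshold=0.8)

    def test_singleton(self):
        out = gene_wise_association(
            self.asn([("s0", "A")]), {"s0": 0.03}, {"A": self.tagset("A", ["s0"])}
        )
        assert out["p"].iloc[0] == pytest.approx(0.03)
        assert out["best_tag"].iloc[0] == "s0"

    def test_min_over_tags(self):
        out = gene_wise_association(
            self.asn([(f"s{j}", "A") for j in range(3)]),
            {"s0": 0.5, "s1": 0.01, "s2": 0.2},
            {"A": self.tagset("A", ["s0", "s1", "s2"])},
        )
        assert out["p"].iloc[0] == pytest.approx(0.01)
        assert out["n_tags"].iloc[0] == 3

    def test_random_fixture_brute_force_min(self):
        rng = np.random.default_rng(7)
        pairs, tagsets, pvals = [], {}, {}
        for g in range(20):
            gid = f"G{g}"
            snps = [f"g{g}_s{j}" for j in range(int(rng.integers(1, 6)))]
            pairs += [(s, gid) for s in snps]
            tagsets[gid] = self.tagset(gid, snps)
            for s in snps:
                pvals[s] = float(rng.uniform(0.001, 1.0))
        out = gene_wise_association(self.asn(pairs), pvals, tagsets).set_index("gene_id")
        for gid, ts in tagsets.items():
            assert out.loc[gid, "p"] == pytest.approx(min(pvals[s] for s in ts.tags))

    def test_missing_pvalue_raises(self):
        with pytest.raises(ConsistencyError):
            gene_wise_association(
                self.asn([("s0", "A")]), {}, {"A": self.tagset("A", ["s0"])}
            )
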
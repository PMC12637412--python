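"""Query-set construction, weighted enrichment, WTCS, NCS/tau and queries."""

import numpy as np
import pandas as pd
import pytest

from cmapneuro import (
    DEGTable,
    NoOverlapError,
    QueryGeneSets,
    TouchstoneReference,
    build_query_sets,
    ncs_tau,
    query,
    query_sets_from_signature,
    touchstone_similarity,
    weighted_es,
    wtcs,
)

from conftest import sig_matrix


def brute_force_es(z: pd.Series, gene_set) -> float:
    """Independent running-sum oracle: rank genes by z descending, walk the
    list accumulating |z|-weighted hits and uniform misses, return the
    extremum of largest magnitude."""
    items = sorted(z.items(), key=lambda kv: -kv[1])
    members = [g in gene_set for g, _ in items]
    n_hit = sum(members)
    n_miss = len(items) - n_hit
    denom = sum(abs(v) for (g, v), m in zip(items, members) if m)
    running, best = 0.0, 0.0
    for (g, v), m in zip(items, members):
        if m:
            running += (abs(v) / denom) if denom > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def random_signature(rng, n_genes):
    genes = [f"g{i}" for i in range(n_genes)]
    return pd.Series(rng.normal(size=n_genes), index=genes)


class TestBuildQuerySets:
    def _degs(self, log2fcs, seed=0):
        df = pd.DataFrame({
            "gene_symbol": [f"G{i}" for i in range(len(log2fcs))],
            "log2fc": log2fcs,
            "significance": 0.001,
        })
        return DEGTable(records=df, significance_kind="fdr")

    def test_full_sets_by_abs_sort(self):
        rng = np.random.default_rng(6)
        fc = np.concatenate([rng.uniform(0.1, 4, 500), -rng.uniform(0.1, 4, 413)])
        degs = self._degs(fc)
        q = build_query_sets(degs, n_up=150, n_down=150, sort_key="abs_log2fc")
        assert len(q.up) == 150 and len(q.down) == 150
        # the up set holds the 150 largest positive fold changes
        pos_sorted = np.sort(fc[fc > 0])[::-1]
        chosen = sorted((degs.records.set_index("gene_symbol").loc[list(q.up),
                                                                   "log2fc"]))
        assert min(chosen) >= pos_sorted[149] - 1e-12

    def test_truncation_when_fewer_positives(self):
        fc = np.concatenate([np.linspace(0.1, 2, 137), -np.linspace(0.1, 3, 300)])
        q = build_query_sets(self._degs(fc), n_up=150, n_down=150)
        assert len(q.up) == 137
        assert len(q.down) == 150

    def test_signed_sort_orders_negatives_ascending(self):
        fc = [3.0, 1.0, 0.5, -0.2, -1.0, -4.0]
        q = build_query_sets(self._degs(fc), n_up=2, n_down=2,
                             sort_key="signed_log2fc")
        recs = self._degs(fc).records.set_index("gene_symbol")
        assert set(recs.loc[list(q.up), "log2fc"]) == {3.0, 1.0}
        assert set(recs.loc[list(q.down), "log2fc"]) == {-4.0, -1.0}

    def test_one_sided_table_rejected(self):
        with pytest.raises(ValueError, match="both positive and negative"):
            build_query_sets(self._degs([1.0, 2.0, 3.0]))


class TestWeightedES:
    def test_top_gene_singleton_set(self):
        rng = np.random.default_rng(7)
        z = random_signature(rng, 20)
        top = z.idxmax()
        es = weighted_es(z, {top})
        assert es > 0
        assert es == brute_force_es(z, {top})

    def test_oracle_equivalence_randomized(self):
        """Exact agreement with the brute-force running sum on 500 random
        (signature, set) instances."""
        rng = np.random.default_rng(17)
        for _ in range(500):
            n = int(rng.integers(5, 101))
            z = random_signature(rng, n)
            k = int(rng.integers(1, min(20, n - 1) + 1))
            gene_set = set(rng.choice(z.index, size=k, replace=False))
            assert weighted_es(z, gene_set) == pytest.approx(
                brute_force_es(z, gene_set), abs=1e-12)

    def test_whole_signature_set_is_degenerate(self):
        rng = np.random.default_rng(9)
        z = random_signature(rng, 15)
        assert weighted_es(z, set(z.index)) == 1.0

    def test_order_reversal_flips_extreme_set_sign(self):
        rng = np.random.default_rng(10)
        z = random_signature(rng, 50)
        top5 = set(z.sort_values(ascending=False).index[:5])
        es_fwd = weighted_es(z, top5)
        es_rev = weighted_es(-z, top5)
        assert es_fwd > 0 > es_rev

    def test_no_overlap_raises(self):
        rng = np.random.default_rng(11)
        z = random_signature(rng, 10)
        with pytest.raises(NoOverlapError):
            weighted_es(z, {"absent_gene"})


class TestWtcs:
    def test_extreme_sets_score_high(self):
        rng = np.random.default_rng(13)
        z = random_signature(rng, 100)
        ordered = z.sort_values(ascending=False)
        q = QueryGeneSets(up=frozenset(ordered.index[:10]),
                          down=frozenset(ordered.index[-10:]))
        es_up, es_down, w = wtcs(z, q)
        assert es_up > 0 > es_down
        assert w > 0.9
        assert w == pytest.approx((brute_force_es(z, q.up)
                                   - brute_force_es(z, q.down)) / 2)

    def test_same_sign_es_gives_zero(self):
        rng = np.random.default_rng(14)
        z = random_signature(rng, 100)
        ordered = z.sort_values(ascending=False)
        q = QueryGeneSets(up=frozenset(ordered.index[:10]),
                          down=frozenset(ordered.index[10:20]))
        es_up, es_down, w = wtcs(z, q)
        assert es_up * es_down > 0
        assert w == 0.0

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            z = random_signature(rng, 60)
            genes = list(z.index)
            up = frozenset(rng.choice(genes, 8, replace=False))
            down = frozenset(rng.choice([g for g in genes if g not in up], 8,
                                        replace=False))
            _, _, w1 = wtcs(z, QueryGeneSets(up=up, down=down))
            _, _, w2 = wtcs(z, QueryGeneSets(up=down, down=up))
            assert w1 == pytest.approx(-w2, abs=1e-12)

    def test_invariance_under_positive_rescaling(self):
        rng = np.random.default_rng(16)
        z = random_signature(rng, 80)
        ordered = z.sort_values(ascending=False)
        q = QueryGeneSets(up=frozenset(ordered.index[:10]),
                          down=frozenset(ordered.index[-10:]))
        _, _, w1 = wtcs(z, q)
        _, _, w2 = wtcs(z * 7.5, q)
        assert w1 == pytest.approx(w2, abs=1e-9)


class TestNcsTau:
    def _corpus(self, n_sigs=12, n_genes=40, seed=19, cell_lines=("A",)):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        ids = [f"sig{i}" for i in range(n_sigs)]
        perts = [f"cp{i % (n_sigs // len(cell_lines))}" for i in range(n_sigs)]
        vals = rng.normal(size=(n_genes, n_sigs))
        m = sig_matrix(vals, genes, ids, perts)
        for i, s in enumerate(m.samples):
            object.__setattr__(s, "cell_line", cell_lines[i % len(cell_lines)])
        return TouchstoneReference(signatures=m)

    def test_counting_example(self):
        corpus = self._corpus(n_sigs=1)
        sid = corpus.signatures.sample_ids[0]
        stratum = corpus.stratum_of(sid)
        corpus.ncs_reference[stratum] = np.array([1.0, 2.0, 3.0, 4.0])
        raw = pd.DataFrame({"signature_id": [sid], "wtcs": [0.4]})
        out = ncs_tau(raw, corpus)
        # single positive score: ncs = wtcs / mean(|wtcs| same sign) = 1.0 — so
        # scale the reference instead to probe the counting rule at |ncs| = 2.5
        corpus.ncs_reference[stratum] = np.array([0.2, 0.5, 3.0, 4.0])
        out = ncs_tau(raw, corpus)
        assert out["ncs"].iloc[0] == pytest.approx(1.0)
        assert out["tau"].iloc[0] == pytest.approx(100 * 2 / 4)

    def test_extremes_and_zero(self):
        corpus = self._corpus(n_sigs=3)
        ids = corpus.signatures.sample_ids
        stratum = corpus.stratum_of(ids[0])
        corpus.ncs_reference[stratum] = np.array([0.1, 0.2, 0.3])
        raw = pd.DataFrame({"signature_id": ids, "wtcs": [0.9, -0.9, 0.0]})
        out = ncs_tau(raw, corpus).set_index("signature_id")
        assert out.loc[ids[0], "tau"] == 100.0
        assert out.loc[ids[1], "tau"] == -100.0
        assert out.loc[ids[2], "tau"] == 0.0
        assert np.sign(out["tau"]).tolist() == np.sign(out["ncs"]).tolist()

    def test_tau_monotone_in_abs_ncs(self):
        corpus = self._corpus(n_sigs=8)
        ids = corpus.signatures.sample_ids
        raw = pd.DataFrame({
            "signature_id": ids,
            "wtcs": [0.1, 0.2, 0.4, 0.8, -0.1, -0.3, -0.5, 0.05],
        })
        out = ncs_tau(raw, corpus)
        pos = out[out["ncs"] > 0].sort_values("ncs")
        assert pos["tau"].is_monotonic_increasing
        assert out["tau"].between(-100, 100).all()


class TestQuery:
    def _corpus(self, n_perts=30, n_genes=100, seed=23, n_cell_lines=2):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        ids, perts, cols = [], [], []
        for p in range(n_perts):
            base = rng.normal(size=n_genes)
            for c in range(n_cell_lines):
                ids.append(f"cp{p}_cl{c}")
                perts.append(f"cp{p}")
                cols.append(base + 0.3 * rng.normal(size=n_genes))
        m = sig_matrix(np.column_stack(cols), genes, ids, perts)
        for i, s in enumerate(m.samples):
            object.__setattr__(s, "cell_line", f"CL{i % n_cell_lines}")
        return TouchstoneReference(signatures=m), rng

    def test_self_query_ranks_source_first(self):
        corpus, rng = self._corpus()
        sid = corpus.signatures.sample_ids[4]
        q = query_sets_from_signature(corpus.signatures.values[sid], n=15)
        per_sig, agg = query(q, corpus)
        assert agg.iloc[0]["pert_id"] == "cp2"  # sid = cp2_cl0
        assert agg.iloc[0]["label"] == "mimic"

    def test_sign_flipped_corpus_reverses(self):
        corpus, rng = self._corpus(n_perts=10, n_cell_lines=1)
        sigs = corpus.signatures
        src = sigs.sample_ids[0]
        q = query_sets_from_signature(sigs.values[src], n=15)
        flipped = sig_matrix(-sigs.values.to_numpy(), sigs.gene_ids,
                             sigs.sample_ids, [f"cp{i}" for i in range(10)])
        ref = TouchstoneReference(signatures=flipped)
        per_sig, agg = query(q, ref)
        row = agg[agg["pert_id"] == "cp0"]
        assert row["median_tau"].iloc[0] < 0
        assert agg.iloc[-1]["pert_id"] == "cp0"

    def test_dropped_offpanel_genes_logged(self, caplog):
        corpus, rng = self._corpus(n_perts=5, n_cell_lines=1)
        sid = corpus.signatures.sample_ids[0]
        base = query_sets_from_signature(corpus.signatures.values[sid], n=10)
        q = QueryGeneSets(up=frozenset(base.up | {"OFFPANEL1"}),
                          down=frozenset(base.down | {"OFFPANEL2"}))
        per_sig, agg = query(q, corpus)
        assert agg.iloc[0]["pert_id"] == "cp0"

    def test_fully_offpanel_query_raises(self):
        corpus, rng = self._corpus(n_perts=5, n_cell_lines=1)
        q = QueryGeneSets(up=frozenset({"X1"}), down=frozenset({"X2"}))
        with pytest.raises(NoOverlapError):
            query(q, corpus)


class TestTouchstone:
    def test_duplicate_signature_ranks_first(self):
        rng = np.random.default_rng(29)
        genes = [f"g{i}" for i in range(60)]
        base = rng.normal(size=60)
        cols = [base] + [rng.normal(size=60) for _ in range(8)] + [base]
        ids = [f"s{i}" for i in range(10)]
        perts = ["target"] + [f"cp{i}" for i in range(8)] + ["twin"]
        m = sig_matrix(np.column_stack(cols), genes, ids, perts)
        corpus = TouchstoneReference(signatures=m)
        ranking = touchstone_similarity("target", corpus, set_size=15)
        assert ranking.iloc[0]["pert_id"] == "twin"

    def test_orthogonal_corpus_taus_center_near_zero(self):
        rng = np.random.default_rng(31)
        genes = [f"g{i}" for i in range(80)]
        cols = rng.normal(size=(80, 20))
        m = sig_matrix(cols, genes, [f"s{i}" for i in range(20)],
                       [f"cp{i}" for i in range(20)])
        corpus = TouchstoneReference(signatures=m)
        ranking = touchstone_similarity("cp0", corpus, set_size=10)
        assert abs(ranking["median_tau"].median()) < 40

    def test_per_stratum_gives_one_ranking_per_cell_line(self):
        rng = np.random.default_rng(37)
        genes = [f"g{i}" for i in range(40)]
        cols = rng.normal(size=(40, 8))
        ids = [f"s{i}" for i in range(8)]
        perts = [f"cp{i // 2}" for i in range(8)]
        m = sig_matrix(cols, genes, ids, perts)
        for i, s in enumerate(m.samples):
            object.__setattr__(s, "cell_line", f"CL{i % 2}")
        corpus = TouchstoneReference(signatures=m)
        ranking = touchstone_similarity("cp1", corpus, per_stratum=True, set_size=8)
        assert set(ranking["query_cell_line"]) == {"CL0", "CL1"}

    def test_unknown_pert_lists_near_matches(self):
        rng = np.random.default_rng(41)
        genes = [f"g{i}" for i in range(20)]
        m = sig_matrix(rng.normal(size=(20, 3)), genes, ["a", "b", "c"],
                       ["AMG-925", "cpX", "cpY"])
        corpus = TouchstoneReference(signatures=m)
        with pytest.raises(KeyError, match="AMG"):
            touchstone_similarity("amg925x", corpus)
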
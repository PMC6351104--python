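"""Depletion calling: counting, threshold rules, NB exact test calibration."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import srnakit as sk


class TestCountAntisense22G:
    def test_counts_match_truth_exactly(self, small_bundle, small_index):
        cfg = sk.SimulationConfig(depth=4000, seed=21)
        reads, truth = sk.simulate_small_rna_library(small_bundle, cfg, "WT")
        inserts, _ = sk.process_reads(reads, barcode=cfg.barcode)
        hits, _ = sk.classify_library(inserts, small_bundle, small_index)
        counts = sk.count_antisense_22g(hits, small_bundle)
        planted = truth[truth["class"] == "22G"].groupby("gene_id").size()
        assert np.array_equal(
            counts.reindex(planted.index).to_numpy(), planted.to_numpy()
        )
        assert counts.sum() == planted.sum()

    def test_sense_strand_read_not_counted(self, small_bundle):
        g = small_bundle.genes[0]
        hits = pd.DataFrame(
            [
                ("r1", g.chrom, g.start + 50, "-" if g.strand == "+" else "+",
                 22, "G", 1, 1.0, "22G", True),
                ("r2", g.chrom, g.start + 80, g.strand, 22, "G", 1, 1.0, "22G", True),
            ],
            columns=["read_id", "chrom", "start", "strand", "length",
                     "first_nt", "n_hits", "weight", "class", "is_best"],
        )
        counts = sk.count_antisense_22g(hits, small_bundle)
        assert counts[g.id] == 1.0  # only the antisense read


class TestSimpleRule:
    @pytest.mark.parametrize(
        "wt,mut,called",
        [
            (20.0, 9.0, True),
            (20.0, 10.0, True),   # boundary inclusive: "at least 2-fold"
            (9.0, 0.0, False),    # below the 10-rpm wild-type floor
            (20.0, 10.1, False),
        ],
    )
    def test_boundaries(self, wt, mut, called):
        res = sk.call_depleted_simple({"g": wt}, {"g": mut})
        assert bool(res.loc["g", "called"]) is called

    def test_missing_gene_is_zero_rpm(self):
        res = sk.call_depleted_simple({"a": 20.0}, {"b": 5.0})
        assert bool(res.loc["a", "called"])  # mut treated as 0
        assert not bool(res.loc["b", "called"])  # wt treated as 0

    def test_monotone_in_mut_rpm(self):
        base = sk.call_depleted_simple({"g": 30.0}, {"g": 15.0})
        assert bool(base.loc["g", "called"])
        for lower in (10.0, 5.0, 0.0):
            res = sk.call_depleted_simple({"g": 30.0}, {"g": lower})
            assert bool(res.loc["g", "called"])  # lowering mut never un-calls


class TestIpRule:
    @pytest.mark.parametrize(
        "ip,inp,called",
        [(20.0, 10.0, True), (9.0, 1.0, False), (10.0, 0.0, True)],
    )
    def test_boundaries(self, ip, inp, called):
        res = sk.call_enriched_ip({"g": ip}, {"g": inp})
        assert bool(res.loc["g", "called"]) is called


class TestNbExactTest:
    def test_symmetric_gene(self):
        wt = pd.DataFrame([[100, 100, 100], [80, 120, 95]],
                          index=["a", "b"], columns=["r1", "r2", "r3"])
        res = sk.nb_exact_test(wt, wt.copy())
        assert res.loc["a", "p"] == pytest.approx(1.0, abs=1e-9)
        assert res.loc["a", "fold_change"] == pytest.approx(1.0)

    def test_all_zero_gene(self):
        wt = pd.DataFrame([[0, 0, 0], [50, 60, 40]],
                          index=["z", "b"], columns=["r1", "r2", "r3"])
        res = sk.nb_exact_test(wt, wt.copy())
        assert res.loc["z", "p"] == 1.0
        assert np.isnan(res.loc["z", "fold_change"])

    def test_requires_two_replicates(self):
        wt = pd.DataFrame([[100]], index=["a"], columns=["r1"])
        with pytest.raises(ValueError):
            sk.nb_exact_test(wt, wt.copy())

    def test_null_pvalues_uniform(self):
        genes = [f"g{i}" for i in range(2000)]
        wt, mut = sk.simulate_count_table(genes, 3, 0.1, seed=31)
        res = sk.nb_exact_test(wt, mut)
        from scipy.stats import kstest

        assert kstest(res["p"], "uniform").pvalue > 0.01

    def test_strong_signal_detected(self):
        genes = [f"g{i}" for i in range(200)]
        depl = {g: 0.25 for g in genes[:20]}
        wt, mut = sk.simulate_count_table(genes, 3, 0.1, depleted_genes=depl, seed=32)
        res = sk.nb_exact_test(wt, mut)
        assert (res.loc[list(depl), "p"] < 1e-3).mean() > 0.9


class TestReplicateRule:
    def test_called_set_respects_all_criteria(self):
        genes = [f"g{i}" for i in range(500)]
        depl = {g: 0.25 for g in genes[:50]}
        wt, mut = sk.simulate_count_table(genes, 3, 0.1, depleted_genes=depl, seed=33)
        res = sk.call_depleted_replicates(wt, mut)
        called = res[res["called"]]
        assert (called["q"] < 0.05).all()
        assert (called["fold_change"] < 0.5).all()
        assert (called["wt_rpm_max"] >= 10).all()
        recovered = set(called.index) & set(depl)
        assert len(recovered) / len(depl) > 0.8

    def test_rpm_floor_blocks_calls(self):
        # one strongly depleted but rare gene below the wild-type rpm floor
        genes = [f"g{i}" for i in range(400)]
        mu = np.full(400, 3000.0)
        mu[0] = 5.0  # ~4 rpm expected: below the 10-rpm wild-type floor
        wt, mut = sk.simulate_count_table(genes, 3, 0.05,
                                          depleted_genes={"g0": 0.1}, seed=34, mu=mu)
        res = sk.call_depleted_replicates(wt, mut)
        assert res.loc["g0", "wt_rpm_max"] < 10
        assert not bool(res.loc["g0", "called"])


def test_agreement_with_edger_oracle(tmp_path):
    """Independent cross-check: edgeR's exact test on the same planted table
    calls essentially the same depleted set (constructions differ, so exact
    p-value equality is not expected)."""
    genes = [f"g{i}" for i in range(300)]
    depl = {g: 0.25 for g in genes[:30]}
    wt, mut = sk.simulate_count_table(genes, 3, 0.1, depleted_genes=depl, seed=35)
    res = sk.call_depleted_replicates(wt, mut)
    ours = set(res[res["called"]].index)

    counts = pd.concat([wt.add_prefix("wt_"), mut.add_prefix("mut_")], axis=1)
    counts_path = tmp_path / "counts.tsv"
    counts.to_csv(counts_path, sep="\t")
    out_path = tmp_path / "edger.tsv"
    script = textwrap.dedent(f"""
        suppressMessages(library(edgeR))
        x <- read.delim("{counts_path}", row.names=1)
        group <- factor(c("wt","wt","wt","mut","mut","mut"), levels=c("wt","mut"))
        y <- DGEList(counts=x, group=group)
        y <- estimateCommonDisp(y)
        et <- exactTest(y)
        tab <- topTags(et, n=Inf)$table
        out <- cbind(gene=rownames(tab), tab)
        write.table(out, "{out_path}", sep="\\t", quote=FALSE, row.names=FALSE)
    """)
    r_file = tmp_path / "run.R"
    r_file.write_text(script)
    subprocess.run(["Rscript", str(r_file)], check=True, capture_output=True)
    tab = pd.read_csv(out_path, sep="\t")
    edger_called = set(tab.loc[(tab["FDR"] < 0.05) & (tab["logFC"] < -1), "gene"])
    jaccard = len(ours & edger_called) / max(len(ours | edger_called), 1)
    assert jaccard >= 0.7
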
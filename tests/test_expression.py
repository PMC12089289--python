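import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from vdindex.expression import (
    CPMMatrix,
    bh_adjust,
    cpm,
    filter_genes,
    mds_embed,
    paired_de,
    participant_log2fc,
    tmm_factors,
)
from vdindex.io import CohortValidationError, GeneAnnotation
from vdindex.simulate import SimulationConfig, simulate_cohort

from .conftest import coding_annotation, toy_counts


class TestCPM:
    def test_closed_form_value(self):
        vals = np.zeros((2, 2), dtype=int)
        vals[0] = [20, 10]
        vals[1] = [2_000_000 - 20, 10]
        cm = toy_counts(vals, n_pairs=1)
        assert cpm(cm).values.iloc[0, 0] == pytest.approx(10.0)

    def test_single_gene_is_million(self):
        cm = toy_counts(np.array([[5, 17]]), n_pairs=1)
        assert (cpm(cm).values.to_numpy() == 1e6).all()

    def test_column_sums_conserved(self):
        rng = np.random.default_rng(0)
        cm = toy_counts(rng.integers(0, 50, size=(10, 4)) + 1, n_pairs=2)
        sums = cpm(cm).values.sum(axis=0)
        assert np.allclose(sums, 1e6)

    def test_all_zero_sample_rejected(self):
        vals = np.array([[1, 0], [2, 0]])
        cm = toy_counts(vals, n_pairs=1)
        with pytest.raises(CohortValidationError, match="all-zero"):
            cpm(cm)


class TestFilterGenes:
    def _cpm(self, rows, gene_ids):
        cm = toy_counts(np.array(rows), n_pairs=2, gene_ids=gene_ids)
        return cpm(cm)

    def test_rules_by_hand_enumeration(self):
        # 5 genes x 4 samples (2 pairs); library sizes equalized by filler gene
        rows = [
            [30, 30, 30, 30],     # g0: CPM well above 10 both timepoints
            [1, 1, 1, 1],         # g1: low expression
            [30, 30, 30, 30],     # g2: high but non-coding
            [2, 30, 2, 30],       # g3: above 10 only at d1
            [30, 30, 30, 30],     # g4: high but no genomic position
        ]
        filler = [1_000_000 - sum(r[j] for r in rows) for j in range(4)]
        gene_ids = ["g0", "g1", "g2", "g3", "g4", "filler"]
        cpm_m = self._cpm(rows + [filler], gene_ids)
        ann = pd.DataFrame(
            {
                "symbol": gene_ids,
                "biotype": ["protein_coding", "protein_coding", "lncRNA",
                            "protein_coding", "protein_coding", "protein_coding"],
                "has_position": [True, True, True, True, False, True],
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
        mask = filter_genes(cpm_m, GeneAnnotation(ann))
        assert mask.tolist() == [True, False, False, False, False, True]

    def test_mean_exactly_at_threshold_excluded(self):
        rows = [[10, 10, 10, 10], [1_000_000 - 10] * 4]
        cpm_m = self._cpm(rows, ["edge", "filler"])
        mask = filter_genes(cpm_m, coding_annotation(["edge", "filler"]))
        assert not mask["edge"]  # strict inequality


class TestTMM:
    def test_identical_samples_factor_one(self):
        vals = np.tile(np.array([[10], [200], [3000]]), (1, 4))
        cm = toy_counts(vals, n_pairs=2)
        assert np.allclose(tmm_factors(cm), 1.0)

    def test_pure_depth_change_factor_one(self):
        rng = np.random.default_rng(1)
        base = rng.integers(10, 1000, size=(50, 1))
        vals = np.hstack([base, base * 3, base, base])
        cm = toy_counts(vals, n_pairs=2)
        assert np.allclose(tmm_factors(cm), 1.0, atol=1e-6)

    def test_matches_bruteforce_trimmed_mean(self):
        # 50 genes, one spiked in sample 0; independent re-coding of the recipe
        rng = np.random.default_rng(7)
        vals = rng.integers(50, 500, size=(50, 4))
        vals[0, 0] = 40_000
        cm = toy_counts(vals, n_pairs=2)
        factors = tmm_factors(cm, reference="s1_d0")

        lib = vals.sum(axis=0).astype(float)
        ref, n_ref = vals[:, 2].astype(float), lib[2]  # s1_d0 is column 2
        expected = []
        for j in range(4):
            obs, n_obs = vals[:, j].astype(float), lib[j]
            m = np.log2((obs / n_obs) / (ref / n_ref))
            a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
            w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
            if np.ptp(m) < 1e-10:
                expected.append(0.0)
                continue
            keep = np.ones(len(m), bool)
            for arr, trim in ((m, 0.30), (a, 0.05)):
                lo, hi = np.quantile(arr, [trim, 1 - trim])
                keep &= (arr >= lo) & (arr <= hi)
            expected.append(np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
        expected = np.array(expected)
        expected -= expected.mean()
        assert np.allclose(factors.to_numpy(), 2.0**expected, atol=1e-6)

    def test_edger_agrees_on_spiked_fixture(self, tmp_path):
        # independent oracle: edgeR's calcNormFactors on the same counts
        rng = np.random.default_rng(7)
        vals = rng.integers(50, 500, size=(50, 4))
        vals[0, 0] = 40_000
        cm = toy_counts(vals, n_pairs=2)
        ours = tmm_factors(cm, reference="s1_d0")
        np.savetxt(tmp_path / "counts.txt", vals, fmt="%d")
        script = textwrap.dedent(
            """
            suppressMessages(library(edgeR))
            x <- as.matrix(read.table("counts.txt"))
            f <- calcNormFactors(x, method="TMM", refColumn=3,
                                 logratioTrim=0.3, sumTrim=0.05, doWeighting=TRUE)
            cat(sprintf("%.10f", f), sep="\\n")
            """
        )
        (tmp_path / "tmm.R").write_text(script)
        out = subprocess.run(
            ["Rscript", "tmm.R"], cwd=tmp_path, capture_output=True, text=True
        )
        if out.returncode != 0:
            pytest.skip(f"Rscript unavailable: {out.stderr[:200]}")
        theirs = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(ours.to_numpy(), theirs, rtol=0.02)


class TestParticipantLog2FC:
    def _cpm_from(self, d0_col, d1_col):
        vals = pd.DataFrame({"s0_d0": d0_col, "s0_d1": d1_col},
                            index=[f"g{i}" for i in range(len(d0_col))])
        sm = pd.DataFrame(
            {"participant_id": ["p0", "p0"], "timepoint": ["d0", "d1"]},
            index=pd.Index(["s0_d0", "s0_d1"], name="sample_id"),
        )
        return CPMMatrix(values=vals, norm_factors=pd.Series(1.0, index=sm.index),
                         sample_map=sm)

    def test_equal_profiles_give_zero(self):
        fc = participant_log2fc(self._cpm_from([5.0, 80.0], [5.0, 80.0]))
        assert (fc.values.to_numpy() == 0).all()

    def test_closed_forms(self):
        fc = participant_log2fc(self._cpm_from([99.5, 0.0], [199.5, 9.5]))
        assert fc.values.iloc[0, 0] == pytest.approx(1.0)
        assert fc.values.iloc[0, 1] == pytest.approx(np.log2(10 / 0.5))


@pytest.fixture(scope="module")
def null_de():
    cfg = SimulationConfig(
        n_genes=3000, n_targets=10, class_effect_means=(0.0, 0.0, 0.0),
        effect_sd=0.0, seed=23,
    )
    counts, _, _, _ = simulate_cohort(cfg)
    return paired_de(cpm(counts))


class TestPairedDE:
    def test_type_one_error_near_nominal(self, null_de):
        frac = null_de["sig_p05"].mean()
        assert 0.03 < frac < 0.07

    def test_treat_dominates_and_reduces_at_zero(self, null_de):
        assert (null_de["p_treat"] >= null_de["p_raw"] - 1e-12).all()
        cfg = SimulationConfig(n_genes=300, n_targets=10, seed=23)
        counts, _, _, _ = simulate_cohort(cfg)
        de0 = paired_de(cpm(counts), tau=0.0)
        assert np.allclose(de0["p_treat"], de0["p_raw"], atol=1e-12)

    def test_injected_signal_gene_ranks_first(self):
        rng = np.random.default_rng(3)
        n_pairs, g = 45, 400
        base = rng.lognormal(np.log(200), 0.3, size=g)
        noise = rng.normal(0, 0.15, size=(g, 2 * n_pairs))
        logv = np.log2(base)[:, None] + noise
        logv[0, 1::2] += 1.0  # one true log2FC = 1 gene at d1
        vals = np.round(2.0**logv).astype(int)
        cm = toy_counts(vals, n_pairs=n_pairs)
        de = paired_de(cpm(cm))
        assert de.iloc[0]["gene_id"] == "g0"

    def test_matches_limma_moderated_t(self, tmp_path):
        # independent oracle: limma eBayes/treat on the same paired deltas
        cfg = SimulationConfig(n_genes=400, n_targets=40, seed=31)
        counts, _, _, _ = simulate_cohort(cfg)
        cpm_m = cpm(counts)
        de = paired_de(cpm_m).set_index("gene_id")
        deltas = participant_log2fc(cpm_m).values.T  # genes x participants
        deltas.to_csv(tmp_path / "deltas.txt", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("deltas.txt", row.names=1))
            fit <- eBayes(lmFit(x), trend=TRUE)
            tr <- treat(lmFit(x), lfc=0.25, trend=TRUE)
            out <- data.frame(gene_id=rownames(x), p=fit$p.value[,1],
                              pt=tr$p.value[,1])
            write.table(out, "limma.txt", sep="\\t", row.names=FALSE, quote=FALSE)
            """
        )
        (tmp_path / "de.R").write_text(script)
        run = subprocess.run(
            ["Rscript", "de.R"], cwd=tmp_path, capture_output=True, text=True
        )
        if run.returncode != 0:
            pytest.skip(f"Rscript unavailable: {run.stderr[:200]}")
        limma = pd.read_csv(tmp_path / "limma.txt", sep="\t").set_index("gene_id")
        joint = de.join(limma)
        r_raw = stats.spearmanr(joint["p_raw"], joint["p"]).statistic
        r_treat = stats.spearmanr(joint["p_treat"], joint["pt"]).statistic
        assert r_raw > 0.98 and r_treat > 0.98
        # significance calls agree closely despite different trend smoothers
        agree = ((joint["p_raw"] < 0.05) == (joint["p"] < 0.05)).mean()
        assert agree > 0.95


class TestBHAdjust:
    def test_hand_computed_triplet(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])),
                           [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_dominates_input_and_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=100)
        ours = bh_adjust(p)
        assert (ours >= p - 1e-12).all()
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(CohortValidationError):
            bh_adjust(np.array([0.5, 1.2]))


class TestMDS:
    def _cpm_of_log(self, logv, n_pairs):
        vals = (2.0**logv) - 0.5  # so log2(CPM + 0.5) reproduces logv exactly
        cm_vals = pd.DataFrame(vals, index=[f"g{i}" for i in range(logv.shape[0])])
        sample_ids, rows = [], []
        for p in range(n_pairs):
            for tp in ("d0", "d1"):
                sid = f"s{p}_{tp}"
                sample_ids.append(sid)
                rows.append({"sample_id": sid, "participant_id": f"p{p}",
                             "timepoint": tp})
        cm_vals.columns = sample_ids
        sm = pd.DataFrame(rows).set_index("sample_id")
        return CPMMatrix(values=cm_vals, norm_factors=pd.Series(1.0, index=sm.index),
                         sample_map=sm)

    def test_identical_samples_coincide(self):
        logv = np.tile(np.array([[3.0], [5.0]]), (1, 4))
        emb = mds_embed(self._cpm_of_log(logv, 2), ["g0", "g1"], k=1)
        assert np.allclose(emb.pairwise_distances, 0.0)
        assert np.allclose(emb.coordinates, emb.coordinates[0])

    def test_collinear_profile_distances_exact(self):
        # one informative gene with log2 values (0, 1, 3, 3): RMSD = |difference|
        logv = np.array([[0.0, 1.0, 3.0, 3.0]])
        emb = mds_embed(self._cpm_of_log(logv, 2), ["g0"], k=1)
        d = emb.pairwise_distances.to_numpy()
        assert d[0, 1] == pytest.approx(1.0)
        assert d[0, 2] == pytest.approx(3.0)
        assert d[1, 2] == pytest.approx(2.0)
        coord = emb.coordinates[:, 0]
        assert np.allclose(np.abs(coord[1] - coord[0]), 1.0, atol=1e-9)

    def test_full_rank_embedding_reconstructs_distances(self):
        rng = np.random.default_rng(9)
        logv = rng.normal(8, 1, size=(30, 6))
        cpm_m = self._cpm_of_log(logv, 3)
        emb = mds_embed(cpm_m, [f"g{i}" for i in range(30)], k=5)
        coords = emb.coordinates
        recon = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(recon, emb.pairwise_distances.to_numpy(), atol=1e-8)

    def test_rank_overflow_rejected(self):
        logv = np.tile(np.array([[3.0], [5.0]]), (1, 4))
        with pytest.raises(CohortValidationError, match="rank"):
            mds_embed(self._cpm_of_log(logv, 2), ["g0", "g1"], k=3)
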
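"""Eigengenes, module-trait screens, GS/MM scores, and keystone logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from peatnet.modtrait import (
    EigengeneSet,
    gene_scores,
    hub_genes,
    keystone_report,
    module_eigengene,
    module_trait_correlation,
)
from peatnet.stats import pearson_with_p
from peatnet.topology import ModulePartition


def make_partition(assignments):
    return ModulePartition(dict(assignments), modularity_q=0.5, isolated=[])


def abundance_frame(rows, taxa=None, samples=None):
    rows = np.asarray(rows, dtype=float)
    taxa = taxa or [f"T{i}" for i in range(rows.shape[0])]
    samples = samples or [f"S{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=taxa, columns=samples)


class TestModuleEigengene:
    def test_rank_one_module_is_fully_explained(self, rng):
        profile = rng.normal(size=12)
        X = abundance_frame([profile, 2 * profile + 1, 0.5 * profile - 3])
        part = make_partition({t: 0 for t in X.index})
        eigs = module_eigengene(X, part)
        eig = eigs[0]
        assert eig.variance_explained == pytest.approx(1.0)
        r = pearson_with_p(eig.scores, profile).r
        assert abs(r) == pytest.approx(1.0)

    def test_sign_anchored_to_mean_member_profile(self, rng):
        X = abundance_frame(rng.normal(size=(5, 15)))
        part = make_partition({t: 0 for t in X.index})
        eig = module_eigengene(X, part)[0]
        Xs = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=0), axis=0)
        assert pearson_with_p(eig.scores, Xs.mean(axis=0)).r > 0

    def test_unit_norm_scores(self, rng):
        X = abundance_frame(rng.normal(size=(4, 10)))
        eig = module_eigengene(X, make_partition({t: 0 for t in X.index}))[0]
        assert np.linalg.norm(eig.scores) == pytest.approx(1.0)

    def test_matches_independent_eigendecomposition_oracle(self, rng):
        # oracle: leading eigenvector of the member covariance across
        # samples, via eigh (a different decomposition than the SVD path)
        X = abundance_frame(rng.normal(size=(3, 9)))
        part = make_partition({t: 0 for t in X.index})
        eig = module_eigengene(X, part)[0]
        Xs = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=0), axis=0)
        A = Xs.to_numpy().T  # samples x members
        w, V = np.linalg.eigh(A @ A.T)
        lead = V[:, np.argmax(w)]
        if np.dot(lead, A.mean(axis=1)) < 0:
            lead = -lead
        assert np.allclose(eig.scores.to_numpy(), lead, atol=1e-8)
        assert eig.variance_explained == pytest.approx(w.max() / w.sum(), abs=1e-10)

    def test_eigengene_beats_any_single_member(self, rng):
        X = abundance_frame(rng.normal(size=(6, 20)))
        part = make_partition({t: 0 for t in X.index})
        eig = module_eigengene(X, part)[0]
        Xs = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=0), axis=0)
        A = Xs.to_numpy()
        total = (A**2).sum()
        for row in A:  # variance captured by projecting onto one member
            u = row / np.linalg.norm(row)
            captured = ((A @ u) ** 2).sum()
            assert eig.variance_explained >= captured / total - 1e-12

    def test_constant_member_dropped_and_small_module_skipped(self, rng):
        X = abundance_frame(
            np.vstack([rng.normal(size=(2, 8)), np.ones((1, 8))]),
        )
        part = make_partition({"T0": 0, "T1": 0, "T2": 1})
        eigs = module_eigengene(X, part)
        assert 0 in eigs and eigs[0].dropped == []
        assert 1 not in eigs  # single constant member -> skipped


class TestModuleTraitCorrelation:
    def test_trait_equal_to_eigengene_has_unit_r(self, rng):
        X = abundance_frame(rng.normal(size=(4, 12)))
        part = make_partition({t: 0 for t in X.index})
        eigs = module_eigengene(X, part)
        traits = pd.DataFrame({"CMR": eigs[0].scores})
        out = module_trait_correlation(eigs, traits)
        row = out[(out.module == 0) & (out.trait == "CMR")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p == pytest.approx(0.0, abs=1e-12)
        assert row.stars == "***"

    def test_independent_trait_respects_null_critical_value(self, rng):
        # at n = 24, P(|r| < r_crit(0.05)) ~ 0.95; assert >= 0.90 over
        # 200 replicates (~5 sd of binomial slack below the mean)
        n = 24
        t_crit = sps.t.ppf(0.975, n - 2)
        r_crit = t_crit / np.sqrt(t_crit**2 + n - 2)
        eig = rng.normal(size=n)
        eig /= np.linalg.norm(eig)
        below = 0
        for _ in range(200):
            trait = rng.normal(size=n)
            below += abs(pearson_with_p(eig, trait).r) < r_crit
        assert below / 200 >= 0.90

    def test_missing_samples_dropped_pairwise(self, rng):
        X = abundance_frame(rng.normal(size=(4, 12)))
        part = make_partition({t: 0 for t in X.index})
        eigs = module_eigengene(X, part)
        traits = pd.DataFrame({"CMR": rng.normal(size=8)}, index=X.columns[:8])
        out = module_trait_correlation(eigs, traits)
        assert out.iloc[0].n == 8

    def test_too_few_pairs_not_computable(self, rng):
        X = abundance_frame(rng.normal(size=(4, 12)))
        part = make_partition({t: 0 for t in X.index})
        eigs = module_eigengene(X, part)
        traits = pd.DataFrame({"CMR": [1.0, 2.0]}, index=X.columns[:2])
        out = module_trait_correlation(eigs, traits)
        assert np.isnan(out.iloc[0].r) and np.isnan(out.iloc[0].p)


class TestGeneScores:
    def fixture(self, rng, n=30):
        X = abundance_frame(rng.normal(size=(5, n)) + 5)
        part = make_partition({t: 0 for t in X.index})
        eigs = module_eigengene(X, part)
        return X, part, eigs

    def test_otu_equal_to_eigengene_has_unit_mm(self, rng):
        X, part, eigs = self.fixture(rng)
        X.loc["T0"] = eigs[0].scores.to_numpy()
        traits = pd.DataFrame({"CMR": rng.normal(size=X.shape[1])}, index=X.columns)
        scores = gene_scores(X, eigs, traits, part)
        assert scores.loc["T0", "mm_r"] == pytest.approx(1.0)
        assert scores.loc["T0", "mm_p"] == pytest.approx(0.0, abs=1e-12)

    def test_otu_equal_to_trait_has_unit_gs(self, rng):
        X, part, eigs = self.fixture(rng)
        trait = X.loc["T2"].to_numpy()
        traits = pd.DataFrame({"CMR": trait}, index=X.columns)
        scores = gene_scores(X, eigs, traits, part)
        assert scores.loc["T2", "gs_r"] == pytest.approx(1.0)
        assert scores.loc["T2", "gs_p"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_per_pair_loop_oracle(self, rng):
        X, part, eigs = self.fixture(rng)
        traits = pd.DataFrame({"CMR": rng.normal(size=X.shape[1])}, index=X.columns)
        scores = gene_scores(X, eigs, traits, part)
        for taxon in X.index:
            r_ref, p_ref = sps.pearsonr(X.loc[taxon], traits["CMR"])
            assert scores.loc[taxon, "gs_r"] == pytest.approx(r_ref, abs=1e-10)
            assert scores.loc[taxon, "gs_p"] == pytest.approx(p_ref, abs=1e-10)
            r_mm, _ = sps.pearsonr(X.loc[taxon], eigs[0].scores)
            assert scores.loc[taxon, "mm_r"] == pytest.approx(r_mm, abs=1e-10)

    def test_constant_otu_flagged_not_raised(self, rng):
        X, part, _ = self.fixture(rng)
        X.loc["T4"] = 1.0
        eigs = module_eigengene(X, part)
        traits = pd.DataFrame({"CMR": rng.normal(size=X.shape[1])}, index=X.columns)
        scores = gene_scores(X, eigs, traits, part)
        assert np.isnan(scores.loc["T4", "gs_r"]) and scores.loc["T4", "constant"]

    def test_unknown_trait_rejected(self, rng):
        X, part, eigs = self.fixture(rng)
        traits = pd.DataFrame({"CMR": rng.normal(size=X.shape[1])}, index=X.columns)
        with pytest.raises(KeyError):
            gene_scores(X, eigs, traits, part, trait_name="CME")

    def test_planted_hub_member_flagged_across_seeds(self):
        # a strong module member in a trait-linked module should satisfy
        # both GS and MM gates in nearly every seeded replicate
        flagged = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 24
            signal = rng.normal(size=n)
            members = np.vstack(
                [0.9 * signal + 0.45 * rng.normal(size=n) for _ in range(6)]
            )
            X = abundance_frame(members)
            part = make_partition({t: 0 for t in X.index})
            eigs = module_eigengene(X, part)
            trait = 0.85 * signal + np.sqrt(1 - 0.85**2) * rng.normal(size=n)
            traits = pd.DataFrame({"CMR": trait}, index=X.columns)
            scores = gene_scores(X, eigs, traits, part)
            flagged += bool(hub_genes(scores).loc["T0"])
        assert flagged >= 45


class TestHubAndKeystoneLogic:
    def scores_frame(self, rows):
        return pd.DataFrame(
            rows, columns=["module", "gs_r", "gs_p", "mm_r", "mm_p"],
            index=[f"T{i}" for i in range(len(rows))],
        )

    def test_hub_gene_truth_table(self):
        scores = self.scores_frame(
            [
                [0, 0.9, 0.01, 0.9, 0.20],   # GS only -> not hub
                [0, 0.9, 0.001, 0.9, 0.001], # both -> hub
                [0, 0.9, 0.20, 0.9, 0.01],   # MM only -> not hub
                [0, np.nan, np.nan, 0.9, 0.001],  # NaN never qualifies
            ]
        )
        assert hub_genes(scores).tolist() == [False, True, False, False]

    @pytest.mark.parametrize(
        "hub, role, function, expected",
        [
            (True, "peripheral", True, True),    # hub-gene branch of the OR
            (False, "connector", True, True),    # critical-node branch
            (True, "module hub", False, False),  # function gate is an AND
            (False, "network hub", True, True),
            (False, "peripheral", True, False),  # neither branch
        ],
    )
    def test_keystone_criteria(self, hub, role, function, expected):
        p = 0.001 if hub else 0.5
        scores = self.scores_frame([[0, 0.9, p, 0.9, p]])
        roles = pd.DataFrame({"role": [role]}, index=["T0"])
        annotations = pd.Series({"T0": function})
        report = keystone_report(scores, roles, annotations)
        assert bool(report.loc["T0", "keystone"]) is expected

    def test_missing_annotation_passes_with_warning_flag(self):
        scores = self.scores_frame([[0, 0.9, 0.001, 0.9, 0.001]])
        roles = pd.DataFrame({"role": ["peripheral"]}, index=["T0"])
        report = keystone_report(scores, roles, annotations=None)
        assert bool(report.loc["T0", "keystone"])
        assert not bool(report.loc["T0", "function_annotated"])
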
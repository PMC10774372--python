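"""Compartment DE, signature enrichment, deconvolution, group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mbenkit.compartments import (
    composition_statistics,
    de_between_compartments,
    deconvolve_bulk,
    signature_enrichment,
)
from mbenkit.synthetic import (
    BulkConfig,
    STATES,
    generate_bulk_compartments,
    normalize_signatures,
    paired_design,
)


def _paired_bulk(seed, n_genes=1000, n_de=100, lfc=1.0, sigma=0.3, n_patients=6):
    rng = np.random.default_rng(seed)
    patients = [f"S{i}" for i in range(n_patients)]
    meta = pd.DataFrame(
        [(p, c) for p in patients for c in ("internodular", "nodular")],
        columns=["patient", "compartment"],
        index=[f"b{i}" for i in range(2 * n_patients)],
    )
    base = rng.uniform(2, 8, n_genes)
    pat_shift = rng.normal(0, 0.5, (n_genes, n_patients))
    true_de = np.zeros(n_genes, bool)
    true_de[:n_de] = True
    Y = np.empty((n_genes, len(meta)))
    for j, (p, c) in enumerate(zip(meta.patient, meta.compartment)):
        y = base + pat_shift[:, patients.index(p)] + rng.normal(0, sigma, n_genes)
        if c == "nodular":
            y[true_de] += lfc
        Y[:, j] = y
    bulk = pd.DataFrame(Y, index=[f"g{i}" for i in range(n_genes)], columns=meta.index)
    return bulk, meta, true_de


class TestCompartmentDE:
    def test_small_fold_change_excluded_despite_significance(self):
        bulk, meta, _ = _paired_bulk(seed=1, n_de=50, lfc=0.4, sigma=0.05)
        table, sets = de_between_compartments(bulk, meta)
        top = table.set_index("gene").loc["g0"]
        assert top.pvalue < 1e-6           # clearly significant ...
        assert not top.significant         # ... but under the 0.5 limit
        assert "g0" not in sets["nodular"]

    def test_planted_genes_sensitivity_and_fdr(self):
        bulk, meta, true_de = _paired_bulk(seed=0)
        _, sets = de_between_compartments(bulk, meta)
        called = set(sets["nodular"]) | set(sets["internodular"])
        tp = sum(1 for g in called if int(g[1:]) < true_de.sum())
        assert tp / true_de.sum() >= 0.9
        assert (len(called) - tp) / max(len(called), 1) <= 0.1

    def test_patient_covariate_calibrates_null(self):
        bulk, meta, _ = _paired_bulk(seed=2, n_de=0, sigma=0.3)
        table, _ = de_between_compartments(bulk, meta)
        fpr = (table.pvalue < 0.05).mean()
        assert abs(fpr - 0.05) < 0.03
        # oracle arm: ignoring the pairing inflates the per-gene variance and
        # collapses power / distorts the null
        naive_p = np.array([
            stats.ttest_ind(
                bulk.loc[g, meta.compartment == "nodular"],
                bulk.loc[g, meta.compartment == "internodular"],
            ).pvalue
            for g in bulk.index[:200]
        ])
        assert naive_p.mean() > table.pvalue[:200].mean()

    def test_confounded_design_refused(self):
        bulk, meta, _ = _paired_bulk(seed=3)
        meta = meta.copy()
        meta["patient"] = np.where(meta.compartment == "nodular", "A", "B")
        with pytest.raises(ValueError, match="confounded|both compartments"):
            de_between_compartments(bulk, meta)


class TestSignatureEnrichment:
    def test_top_two_of_five_scores_one(self):
        profiles = pd.DataFrame({"s": [5.0, 4.0, 3.0, 2.0, 1.0]},
                                index=["a", "b", "c", "d", "e"])
        scores = signature_enrichment(profiles, {"set": ["a", "b"]}, tau=0.0)
        assert scores.loc["set", "s"] == pytest.approx(1.0)

    def test_bottom_genes_score_negative(self):
        profiles = pd.DataFrame({"s": np.arange(20, 0, -1.0)},
                                index=[f"g{i}" for i in range(20)])
        scores = signature_enrichment(profiles, {"set": ["g18", "g19"]})
        assert scores.loc["set", "s"] < 0

    def test_random_sets_match_their_permutation_null(self, rng):
        """Scores of random sets sit inside the central 95% band of the
        permutation null built the same way (two independent batches)."""
        profiles = pd.DataFrame(rng.normal(5, 1, (200, 1)), columns=["s"],
                                index=[f"g{i}" for i in range(200)])

        def batch(n):
            return np.array([
                signature_enrichment(
                    profiles, {"x": list(rng.choice(profiles.index, 15, replace=False))}
                ).loc["x", "s"]
                for _ in range(n)
            ])

        null = batch(300)
        observed = batch(60)
        lo, hi = np.quantile(null, [0.025, 0.975])
        assert lo <= observed.mean() <= hi
        inside = ((observed >= lo) & (observed <= hi)).mean()
        assert inside >= 0.85  # ~95% expected, finite-sample slack


@pytest.fixture(scope="module")
def state_signatures():
    rng = np.random.default_rng(7)
    sig = pd.DataFrame(rng.uniform(0.05, 1.0, (150, 6)),
                       index=[f"g{i}" for i in range(150)], columns=list(STATES))
    # give each state a marker block so the matrix is well conditioned
    for k in range(6):
        sig.iloc[k * 20 : k * 20 + 20, k] += 4.0
    return normalize_signatures(sig)


class TestDeconvolution:
    def test_noiseless_exact_recovery(self, state_signatures):
        design = paired_design()
        cfg = BulkConfig(noise_sd=0.0, proportion_jitter=0.0, batch_sd=0.0, seed=1)
        bulk, props = generate_bulk_compartments(state_signatures, design, cfg)
        out = deconvolve_bulk(bulk, state_signatures)
        assert np.abs(out.proportions.to_numpy() - props.to_numpy()).max() < 1e-6

    def test_one_signature_bulk_is_one_hot(self, state_signatures):
        bulk = state_signatures[["migrating_cgnp"]].rename(columns={"migrating_cgnp": "b0"})
        out = deconvolve_bulk(bulk, state_signatures)
        assert out.proportions.loc["b0", "migrating_cgnp"] == pytest.approx(1.0, abs=1e-9)

    def test_nb_noise_mean_absolute_error(self, state_signatures):
        """12 bulk samples with negative-binomial counting noise."""
        rng = np.random.default_rng(0)
        design = paired_design()
        cfg = BulkConfig(noise_sd=0.0, proportion_jitter=0.02, batch_sd=0.0, seed=2)
        bulk, props = generate_bulk_compartments(state_signatures, design, cfg)
        depth, size = 2e5, 20.0
        mu = bulk.to_numpy() * depth
        noisy = rng.poisson(rng.gamma(size, mu / size))
        noisy_bulk = pd.DataFrame(noisy, index=bulk.index, columns=bulk.columns)
        out = deconvolve_bulk(noisy_bulk, state_signatures)
        mae = np.abs(out.proportions.to_numpy() - props.to_numpy()).mean()
        assert mae <= 0.05

    def test_scale_invariance(self, state_signatures):
        design = paired_design()
        cfg = BulkConfig(noise_sd=0.1, seed=3)
        bulk, _ = generate_bulk_compartments(state_signatures, design, cfg)
        out1 = deconvolve_bulk(bulk, state_signatures)
        out2 = deconvolve_bulk(bulk * 37.5, state_signatures)
        np.testing.assert_allclose(out1.proportions, out2.proportions, atol=1e-9)

    def test_planted_compartment_contrast_signs(self, state_signatures):
        """Internodular bulks are early/proliferating-rich, nodular bulks
        differentiated-rich; the recovered contrast keeps the planted sign."""
        design = paired_design(replicates=2)
        cfg = BulkConfig(noise_sd=0.1, seed=4)
        bulk, props = generate_bulk_compartments(state_signatures, design, cfg)
        out = deconvolve_bulk(bulk, state_signatures)
        nod = design.compartment.to_numpy() == "nodular"
        est_diff = out.proportions[nod].mean() - out.proportions[~nod].mean()
        true_diff = props[nod].mean() - props[~nod].mean()
        assert (np.sign(est_diff) == np.sign(true_diff)).all()

    def test_too_few_states_rejected(self, state_signatures):
        with pytest.raises(ValueError, match="2 states"):
            deconvolve_bulk(state_signatures[["early_cgnp"]],
                            state_signatures[["early_cgnp"]])


class TestCompositionStatistics:
    def test_planted_difference_detected(self, rng):
        vals = pd.DataFrame({
            "stateA": np.r_[rng.normal(0.5, 0.05, 6), rng.normal(0.2, 0.05, 6)]
        }, index=[f"s{i}" for i in range(12)])
        groups = pd.Series(["g1"] * 6 + ["g2"] * 6, index=vals.index)
        out = composition_statistics(vals, groups)
        assert out.pvalue[0] < 0.01

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            vals = pd.DataFrame({"s": rng.normal(0.3, 0.05, 12)},
                                index=[f"s{i}" for i in range(12)])
            groups = pd.Series(["a"] * 6 + ["b"] * 6, index=vals.index)
            pvals.append(composition_statistics(vals, groups).pvalue[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_spearman_for_numeric_covariate(self, rng):
        x = rng.uniform(0, 1, 20)
        vals = pd.DataFrame({"s": 0.2 + 0.5 * x + rng.normal(0, 0.01, 20)},
                            index=[f"s{i}" for i in range(20)])
        cov = pd.Series(x, index=vals.index)
        out = composition_statistics(vals, cov)
        assert out.method[0] == "spearman"
        assert out.statistic[0] > 0.9

    def test_degenerate_groups_reported_na(self):
        vals = pd.DataFrame({"s": [0.5] * 8}, index=[f"s{i}" for i in range(8)])
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=vals.index)
        out = composition_statistics(vals, groups)
        assert np.isnan(out.statistic[0]) and np.isnan(out.pvalue[0])
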
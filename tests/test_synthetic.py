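"""The cohort generator: determinism, planted structure, survival model."""

import numpy as np
import pandas as pd
import pytest

from isomirdiv.diversity import (
    diversity_grouping,
    diversity_matrix,
    filter_low_abundance,
)
from isomirdiv.synthetic import (
    ConfigError,
    SimConfig,
    generate_clinical,
    generate_count_table,
    generate_sequences,
    plant_site_comparison_utr,
    signal_mirnas,
    zero_truncated_poisson_rate,
)
from isomirdiv.targetscan import compare_site_counts, seed_sites

SMALL = dict(n_tumor=30, n_normal=30, n_mirnas=12)


class TestConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_tumor", 0),
            ("diversity_fc", 0.5),
            ("censor_rate", 1.0),
            ("nb_dispersion", -1.0),
            ("n_signal", 99),
        ],
    )
    def test_invalid_values_name_the_field(self, field, value):
        with pytest.raises(ConfigError, match=field):
            SimConfig(**{field: value})

    def test_ztp_rate_inverts_the_truncated_mean(self):
        for mean in (1.5, 3.0, 8.0):
            lam = zero_truncated_poisson_rate(mean)
            assert lam / (1 - np.exp(-lam)) == pytest.approx(mean, abs=1e-9)


class TestCountTable:
    def test_identical_seed_identical_bytes(self, tmp_path):
        a = generate_count_table(SimConfig(seed=3, **SMALL))
        b = generate_count_table(SimConfig(seed=3, **SMALL))
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.counts.to_csv(pa, sep="\t")
        b.counts.to_csv(pb, sep="\t")
        assert pa.read_bytes() == pb.read_bytes()
        assert a.samples.equals(b.samples)

    def test_different_seeds_differ(self):
        a = generate_count_table(SimConfig(seed=3, **SMALL))
        b = generate_count_table(SimConfig(seed=4, **SMALL))
        assert not a.counts.equals(b.counts)

    def test_depth_concentrates_around_mean(self):
        cfg = SimConfig(n_tumor=100, n_normal=10, n_mirnas=12, seed=5)
        totals = generate_count_table(cfg).depths().to_numpy(float)
        assert len(totals) >= 100
        z = np.abs(totals - cfg.depth_mean) / totals.std()
        assert (z <= 4).all() and np.abs(totals.mean() - cfg.depth_mean) < 3 * totals.std() / np.sqrt(len(totals))

    def test_planted_fold_change_recovered_within_20pct(self):
        cfg = SimConfig(n_tumor=60, n_normal=60, seed=11)
        table = filter_low_abundance(generate_count_table(cfg))
        div = diversity_matrix(table)
        t_cols = table.tissue_samples("tumor")
        n_cols = table.tissue_samples("normal")
        for m in signal_mirnas(cfg):
            ratio = div.loc[m, n_cols].mean() / div.loc[m, t_cols].mean()
            assert ratio == pytest.approx(cfg.diversity_fc, rel=0.2)

    def test_five_prime_ends_more_conserved_than_three_prime(self):
        table = generate_count_table(SimConfig(seed=7, **SMALL))
        o5 = table.counts.index.get_level_values("offset5").to_numpy(float)
        o3 = table.counts.index.get_level_values("offset3").to_numpy(float)
        weights = table.counts.sum(axis=1).to_numpy(float)

        def wvar(x):
            m = np.average(x, weights=weights)
            return np.average((x - m) ** 2, weights=weights)

        assert wvar(o3) > wvar(o5)

    def test_null_config_has_no_planted_difference(self):
        cfg = SimConfig(n_signal=0, diversity_fc=1.0, seed=9, **SMALL)
        table = filter_low_abundance(generate_count_table(cfg))
        div = diversity_matrix(table)
        t_cols = table.tissue_samples("tumor")
        n_cols = table.tissue_samples("normal")
        ratios = div[n_cols].mean(axis=1) / div[t_cols].mean(axis=1)
        assert np.abs(np.log(ratios)).mean() < 0.2


class TestClinical:
    def groups_for(self, cfg):
        table = filter_low_abundance(generate_count_table(cfg))
        div = diversity_matrix(table)
        return table, diversity_grouping(div.loc[signal_mirnas(cfg)[0], table.tissue_samples("tumor")])

    def test_no_censoring_means_all_events(self):
        cfg = SimConfig(censor_rate=0.0, seed=2, **SMALL)
        table, groups = self.groups_for(cfg)
        clin = generate_clinical(cfg, groups, table.samples)
        assert (clin["event"] == 1).all()
        assert (clin["time_days"] > 0).all()

    def test_censor_rate_realized(self):
        cfg = SimConfig(n_tumor=400, n_normal=5, n_mirnas=10, censor_rate=0.4, seed=2)
        table, groups = self.groups_for(cfg)
        clin = generate_clinical(cfg, groups, table.samples)
        assert (clin["event"] == 0).mean() == pytest.approx(0.4, abs=0.08)

    def test_missing_labels_listed(self):
        cfg = SimConfig(seed=2, **SMALL)
        table, groups = self.groups_for(cfg)
        with pytest.raises(ValueError, match=groups.index[0]):
            generate_clinical(cfg, groups.iloc[1:], table.samples)

    def test_null_hazard_centers_on_hr_one(self):
        """With unit hazard ratios the Cox estimate on a large cohort is ~1."""
        from isomirdiv.survival import cox_fit

        cfg = SimConfig(n_tumor=500, n_normal=5, n_mirnas=10,
                        hr_diversity=1.0, hr_histology=1.0, censor_rate=0.2, seed=4)
        table, groups = self.groups_for(cfg)
        clin = generate_clinical(cfg, groups, table.samples)
        res = cox_fit(clin, ["diversity_group"])[0]
        assert res.ci_low < 1.0 < res.ci_high

    def test_diversity_hazard_recovered(self):
        cfg = SimConfig(n_tumor=500, n_normal=5, n_mirnas=10,
                        hr_diversity=2.0, censor_rate=0.1, seed=6)
        table, groups = self.groups_for(cfg)
        clin = generate_clinical(cfg, groups, table.samples)
        from isomirdiv.survival import cox_fit

        res = {r.term: r for r in cox_fit(clin, ["diversity_group", "histology"])}
        hr_more = res["diversity_group_more"].hazard_ratio
        assert 1 / hr_more == pytest.approx(2.0, rel=0.35)  # "less" carries the risk
        assert res["histology_unfavorable"].hazard_ratio == pytest.approx(
            cfg.hr_histology, rel=0.35
        )


class TestSequences:
    def test_manifest_is_ground_truth_for_seed_sites(self):
        cfg = SimConfig(seed=8, **SMALL)
        precursors, ann, utrs, manifest = generate_sequences(cfg)
        for _, row in ann.iterrows():
            mature = precursors[row.precursor_id][row.start - 1 : row.end]
            utr_id = f"utr-{row.mirna}"
            n_exact = int(manifest[f"{utr_id}:{row.mirna}:exact"])
            n_mm1 = int(manifest[f"{utr_id}:{row.mirna}:mm1"])
            assert len(seed_sites(mature, utrs[utr_id], max_mismatch=0)) == n_exact
            assert len(seed_sites(mature, utrs[utr_id], max_mismatch=1)) == n_exact + n_mm1

    def test_one_mismatch_sites_invisible_at_zero_budget(self):
        cfg = SimConfig(seed=8, **SMALL)
        precursors, ann, utrs, manifest = generate_sequences(cfg)
        checked = 0
        for _, row in ann.iterrows():
            utr_id = f"utr-{row.mirna}"
            n_mm1 = int(manifest[f"{utr_id}:{row.mirna}:mm1"])
            if n_mm1 == 0:
                continue
            mature = precursors[row.precursor_id][row.start - 1 : row.end]
            h0 = len(seed_sites(mature, utrs[utr_id], max_mismatch=0))
            h1 = len(seed_sites(mature, utrs[utr_id], max_mismatch=1))
            assert h1 - h0 == n_mm1
            checked += 1
        assert checked > 0

    def test_mature_arm_annotated_inside_precursor(self):
        cfg = SimConfig(seed=8, **SMALL)
        precursors, ann, _, _ = generate_sequences(cfg)
        for _, row in ann.iterrows():
            assert 1 <= row.start <= row.end <= len(precursors[row.precursor_id])


class TestSiteComparisonUtr:
    def test_planted_isoform_gain(self, mir455, rng):
        """The archetype/0|1 pair on a planted UTR shows the 5-vs-4 pattern:
        equal seed hits, one extra effective site for the extended isoform."""
        from isomirdiv.nomenclature import IsomirId, isomir_sequence

        _, seq, ann = mir455
        arch = isomir_sequence(seq, ann, IsomirId(ann.mirna_name, 0, 0))
        iso = isomir_sequence(seq, ann, IsomirId(ann.mirna_name, 0, 1))
        utr, frac = plant_site_comparison_utr(arch, iso, rng)
        res = compare_site_counts(arch, iso, utr, max_mismatch=0, min_score_frac=frac)
        assert (res.sites_archetype, res.sites_isoform) == (4, 5)
        assert res.seed_sites_archetype == res.seed_sites_isoform == 5
        assert res.delta == 1

    def test_requires_pure_extension(self, rng):
        with pytest.raises(ValueError):
            plant_site_comparison_utr("ACGUACGUACGUACGUACGUAC", "ACGUACGUACGUACGUACGUAG", rng)
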
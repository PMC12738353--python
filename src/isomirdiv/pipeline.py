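"""End-to-end orchestration: simulate/load -> filter -> diversity -> survival -> scan.

Stages run in a fixed order mirroring the analysis funnel: abundance filter,
pooled isoform-category table with a chi-square tissue comparison,
differential diversity for tumor/normal and unfavorable/favorable, the
candidate intersection, per-isoform expression comparisons for the
candidates, survival stratification by diversity group, and an optional
archetype-vs-isoform target scan.  Every output is tab-separated text plus a
machine-readable JSON summary; the run-log echoes every threshold verbatim.
All randomness flows from the config seed, so a rerun reproduces every output
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import io as iio
from . import survival as sv
from . import targetscan as ts
from .nomenclature import IsomirId, format_name, isomir_sequence
from .synthetic import SimConfig, generate_clinical, generate_count_table, plant_site_comparison_utr

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """Pipeline thresholds and input locations.

    Either ``sim`` (a simulation block) or both ``counts_path`` and
    ``clinical_path`` must be provided.  Thresholds default to the analysis'
    own: >100 reads in >=1 sample, median isoform count >= 3, alpha 0.01 for
    the tumor/normal test, 0.05 for unfavorable/favorable, fold change 2.
    """

    outdir: str = "isomirdiv_run"
    seed: int = 0
    sim: SimConfig | None = None
    counts_path: str | None = None
    clinical_path: str | None = None
    min_reads: int = 100
    min_samples: int = 1
    min_median: float = 3.0
    alpha_tn: float = 0.01
    alpha_uf: float = 0.05
    fc: float = 2.0
    tie_rule: str = "less"
    presence_min: int = 1
    horizon_days: float | None = None
    scan: bool = True
    scan_max_mismatch: int = 0

    def thresholds(self) -> dict:
        return {
            "min_reads": self.min_reads,
            "min_samples": self.min_samples,
            "min_median": self.min_median,
            "alpha_tn": self.alpha_tn,
            "alpha_uf": self.alpha_uf,
            "fc": self.fc,
            "tie_rule": self.tie_rule,
            "presence_min": self.presence_min,
            "horizon_days": self.horizon_days,
            "scan_max_mismatch": self.scan_max_mismatch,
            "seed": self.seed,
        }


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file (flat keys; optional ``sim`` block)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("sim", None)
    cfg = RunConfig(**raw)
    if sim is not None:
        cfg.sim = SimConfig(**sim)
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the machine-readable summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"{k}\t{v}" for k, v in config.thresholds().items()]
    summary: dict = {"thresholds": config.thresholds()}

    # ------------------------------------------------------------------ input
    stage = "input"
    sim: SimConfig | None = None
    try:
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            table = generate_count_table(sim)
        elif config.counts_path:
            counts = iio.read_count_table(config.counts_path)
            ann = iio.read_clinical(config.clinical_path) if config.clinical_path else None
            samples = ann[["tissue", "histology", "gender"]] if ann is not None else None
            table = dv.IsomirCountTable(counts, samples)
        else:
            raise ValueError("config needs a sim block or a counts_path")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    depths = table.depths()

    # ----------------------------------------------------------------- filter
    stage = "filter"
    filtered = dv.filter_low_abundance(table, config.min_reads, config.min_samples)
    iio.write_count_table(filtered.counts, out / "filtered_counts.tsv")
    summary["n_isomirs_raw"] = int(len(table.counts))
    summary["n_isomirs_filtered"] = int(len(filtered.counts))

    # ------------------------------------------------- pooled categories + chi2
    stage = "categories"
    try:
        cat_t = dv.pooled_category_counts(filtered, "tumor")
        cat_n = dv.pooled_category_counts(filtered, "normal")
        # categories empty in both tissues carry no information; drop them
        nonzero = (cat_t + cat_n) > 0
        if nonzero.sum() >= 2:
            chi2, chi_p = dv.contingency_chi_square(cat_t[nonzero], cat_n[nonzero])
        else:
            chi2, chi_p = float("nan"), float("nan")
        cats = pd.DataFrame({"tumor": cat_t, "normal": cat_n})
        _write_tsv(cats, out / "category_counts.tsv")
        _write_tsv(
            pd.DataFrame({"chi_square": [chi2], "p_value": [chi_p]}),
            out / "category_chi_square.tsv",
            index=False,
        )
        summary["category_counts"] = {c: cats[c].tolist() for c in cats.columns}
        summary["category_chi_square_p"] = chi_p
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -------------------------------------------------------------- diversity
    stage = "diversity"
    div = dv.diversity_matrix(filtered, config.presence_min)
    _write_tsv(div, out / "diversity_matrix.tsv")
    eligible = dv.eligible_mirnas(div, config.min_median)
    div_el = div.loc[eligible]
    summary["n_eligible_mirnas"] = len(eligible)

    tissue = filtered.samples["tissue"]
    comp_tn = dv.differential_diversity(
        div_el, tissue, alpha=config.alpha_tn, group_a="tumor", group_b="normal"
    )
    _write_tsv(dv.comparisons_to_frame(comp_tn), out / "diff_diversity_tumor_normal.tsv")

    tumor_ids = filtered.tissue_samples("tumor")
    hist = filtered.samples.loc[tumor_ids, "histology"]
    comp_uf = dv.differential_diversity(
        div_el[tumor_ids], hist, alpha=config.alpha_uf,
        group_a="unfavorable", group_b="favorable",
    )
    _write_tsv(dv.comparisons_to_frame(comp_uf), out / "diff_diversity_unfav_fav.tsv")

    cand_tn = dv.select_candidates(comp_tn, config.fc)
    cand_uf = dv.select_candidates(comp_uf, config.fc)
    shared = dv.intersect_comparisons(cand_tn, cand_uf)
    (out / "candidates_tn.txt").write_text("\n".join(cand_tn) + "\n")
    (out / "candidates_uf.txt").write_text("\n".join(cand_uf) + "\n")
    (out / "candidates_shared.txt").write_text("\n".join(shared) + "\n")
    summary["candidates_tn"] = cand_tn
    summary["candidates_uf"] = cand_uf
    summary["candidates_shared"] = shared

    # --------------------------------------- per-isoform expression comparison
    stage = "isoform_expression"
    rows = []
    for mirna in shared:
        sub = filtered.counts.loc[[mirna]] if mirna in filtered.counts.index.get_level_values(0) else None
        if sub is None:
            continue
        rpm_tab = sub.div(depths, axis=1) * 1e6
        for key, row in rpm_tab.iterrows():
            name = format_name(IsomirId(key[0], key[1], key[2]))
            x = row[tumor_ids].to_numpy(dtype=float)
            y = row[[s for s in filtered.sample_ids if s not in set(tumor_ids)]].to_numpy(dtype=float)
            p = dv._welch_p(x, y, equal_var=False)
            rows.append((name, float(np.mean(x)), float(np.mean(y)), p))
    iso_expr = pd.DataFrame(
        rows, columns=["isomir", "mean_rpm_tumor", "mean_rpm_normal", "p_value"]
    )
    _write_tsv(iso_expr, out / "isoform_expression_comparison.tsv", index=False)

    # ---------------------------------------------------------------- survival
    stage = "survival"
    try:
        focus = shared[0] if shared else (eligible[0] if eligible else None)
        if focus is None:
            summary["survival"] = None
        else:
            groups = dv.diversity_grouping(div.loc[focus, tumor_ids], tie=config.tie_rule)
            if config.clinical_path:
                clinical = iio.read_clinical(config.clinical_path)
                clinical = clinical.loc[[s for s in tumor_ids if s in clinical.index]]
                clinical["diversity_group"] = groups.loc[clinical.index]
            elif sim is not None:
                clinical = generate_clinical(sim, groups, filtered.samples)
            else:
                raise ValueError("no clinical_path and no simulation block")
            if config.horizon_days:
                clinical = sv.apply_horizon(clinical, config.horizon_days)
            iio.write_clinical(clinical, out / "clinical.tsv")

            km_rows = []
            for g in ("more", "less"):
                sel = clinical[clinical["diversity_group"] == g]
                if len(sel):
                    km = sv.km_curve(sel["time_days"], sel["event"])
                    km.insert(0, "group", g)
                    km_rows.append(km)
            _write_tsv(pd.concat(km_rows), out / f"km_{focus}.tsv", index=False)

            lr_stat, lr_p = sv.logrank(
                clinical["time_days"], clinical["event"], clinical["diversity_group"]
            )
            _write_tsv(
                pd.DataFrame({"mirna": [focus], "logrank_chi2": [lr_stat], "p_value": [lr_p]}),
                out / "logrank.tsv", index=False,
            )

            uni = sv.cox_fit(clinical, ["diversity_group"])
            multi = sv.cox_fit(clinical, ["diversity_group", "histology"])
            for name, res in (("cox_univariate", uni), ("cox_multivariable", multi)):
                _write_tsv(
                    pd.DataFrame(
                        [(r.term, r.hazard_ratio, r.ci_low, r.ci_high, r.p_value) for r in res],
                        columns=["term", "hazard_ratio", "ci_low", "ci_high", "p_value"],
                    ),
                    out / f"{name}.tsv", index=False,
                )
            summary["survival"] = {
                "focus_mirna": focus,
                "logrank_p": lr_p,
                "cox_univariate": {r.term: r.hazard_ratio for r in uni},
                "cox_multivariable": {r.term: r.hazard_ratio for r in multi},
            }
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -------------------------------------------------------------------- scan
    stage = "scan"
    if config.scan:
        try:
            prec_id, prec_seq, ann = iio.load_mir455_fixture()
            arch = isomir_sequence(prec_seq, ann, IsomirId(ann.mirna_name, 0, 0))
            iso = isomir_sequence(prec_seq, ann, IsomirId(ann.mirna_name, 0, 1))
            rng = np.random.default_rng((config.seed, 3))
            utr, frac = plant_site_comparison_utr(arch, iso, rng)
            cmp_res = ts.compare_site_counts(
                arch, iso, utr, gene_id="synthetic-utr",
                max_mismatch=config.scan_max_mismatch, min_score_frac=frac,
            )
            _write_tsv(
                pd.DataFrame(
                    [[cmp_res.gene_id, cmp_res.sites_archetype, cmp_res.sites_isoform,
                      cmp_res.delta, cmp_res.seed_sites_archetype, cmp_res.seed_sites_isoform]],
                    columns=["gene", "effective_archetype", "effective_isoform",
                             "delta", "seed_hits_archetype", "seed_hits_isoform"],
                ),
                out / "scan_site_comparison.tsv", index=False,
            )
            summary["scan"] = {
                "archetype": ann.mirna_name + " 0|0",
                "isoform": ann.mirna_name + " 0|1",
                "effective_archetype": cmp_res.sites_archetype,
                "effective_isoform": cmp_res.sites_isoform,
                "delta": cmp_res.delta,
            }
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
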
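"""End-to-end orchestration: matrices/fixtures/simulation in, tables out.

``run_pipeline`` chains the full analysis — parental classification,
additivity scoring, sharing-category partition, loss-origin attribution,
diversity estimation, the band-count statistics and the split network —
and writes table-shaped CSVs plus NEXUS networks and a run log.

``reproduce_tables`` recomputes every derivable printed number from the
packaged count fixtures and emits an observed-vs-printed comparison in
which known discrepancies of the printed tables are whitelisted and
annotated; any other mismatch is flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from hashlib import sha256
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .additivity import (classify_parental_bands, deviation_summary,
                         score_polyploid_deviation, sharing_categories)
from .diversity import DiversityConfig, nei_diversity_profile
from .inference import (chisq_ratio_gof, holm_adjust, newcombe_wilson_ci,
                        oneway_anova_tukey, yates_chisq_2x2)
from .marker_data import (MarkerMatrix, TaxonScheme, load_paper_fixture,
                          load_printed_metadata, read_matrix,
                          read_taxon_scheme)
from .network import bootstrap_confidence_network, write_splits_nexus
from .simulate import default_study_params, load_params, simulate_dataset

__all__ = ["RunConfig", "run_pipeline", "reproduce_tables",
           "table6_anova", "fixture_category_proportions"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one end-to-end run."""

    mode: Literal["matrices", "fixtures", "simulate"]
    output_dir: Path
    matrix_paths: Mapping[str, Path] | None = None   # family -> TSV
    scheme_path: Path | None = None
    sim_params_path: Path | None = None
    alpha: float = 0.05
    n_bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        object.__setattr__(self, "output_dir", Path(self.output_dir))


# ---------------------------------------------------------------------------
# Fixture-based reproduction

#: printed cells known not to match exact recomputation; kept as printed
#: and annotated instead of flagged (rounding slips and one arithmetic
#: inconsistency in the source tables)
_WHITELIST = {
    ("table3", "Ns1", "shared_pct"): "printed 15.1 vs exact 15.15 (truncated)",
    ("table3", "Tnt1", "shared_pct"): "printed 5.3 vs exact 5.36 (rounding slip)",
    ("table3", "TRIM", "shared_pct"): "printed 16.6 vs exact 16.67 (rounding slip)",
    ("table5_new", "TS", "in_all_pct"): "printed 106 vs exact 106.7 (truncated)",
    ("table5_lost", "Tnt1", "NUD+ISL_pct"): "printed 18.6 vs exact 18.52",
    ("table5_lost", "_all_tes", "ISL_pct"):
        "printed 3.4 vs exact 3.70 (inconsistent printed cell)",
}


def _decimals(printed: float) -> int:
    s = f"{printed}"
    return len(s.split(".")[1]) if "." in s else 0


def _compare(table: str, te: str, cell: str, printed: float | None,
             observed: float | None, rows: list[dict],
             tol: float | None = None) -> None:
    if printed is None or observed is None:
        return
    if tol is None:
        tol = 0.5 * 10.0 ** (-_decimals(printed)) + 1e-9
    key = (table, te, cell)
    if key in _WHITELIST:
        rows.append({"table": table, "te": te, "cell": cell,
                     "printed": printed, "observed": round(observed, 4),
                     "match": "whitelisted", "note": _WHITELIST[key]})
        return
    ok = abs(observed - printed) <= tol
    rows.append({"table": table, "te": te, "cell": cell, "printed": printed,
                 "observed": round(observed, 4),
                 "match": "yes" if ok else "MISMATCH", "note": ""})


def fixture_category_proportions(block: Literal["new", "lost"]) -> list[np.ndarray]:
    """Sharing-category proportion groups from the printed deviation counts.

    For each of the 7 sharing categories, the per-family proportions of
    that family's non-additive bands falling in the category (category
    count over the family's "in all" count) — the construction behind
    the printed one-way ANOVA.
    """
    fx = load_paper_fixture("table5_new" if block == "new" else "table5_lost")
    groups = []
    for cat in fx.category_order:
        vals = []
        for te in fx.te_families:
            rec = fx.te_record(te)
            vals.append(rec["categories"][cat][0] / rec["in_all"][0])
        groups.append(np.array(vals))
    return groups


def table6_anova(block: Literal["new", "lost"]):
    """One-way ANOVA across sharing categories built from the printed counts."""
    groups = fixture_category_proportions(block)
    return oneway_anova_tukey(groups)


def reproduce_tables(fixture_ids: Sequence[str] = ("table3", "table5_new",
                                                   "table5_lost")) -> pd.DataFrame:
    """Recompute every derivable printed number and compare with the print.

    Returns a long-format frame with one row per checked cell (printed
    value, recomputed value, match flag, annotation).  Mismatches outside
    the whitelist carry match='MISMATCH'.
    """
    rows: list[dict] = []
    meta = load_printed_metadata()
    for fid in fixture_ids:
        if fid == "table4":
            continue  # printed denominators not recoverable; nothing derivable
        fx = load_paper_fixture(fid)
        if fid == "table3":
            for te in fx.te_families:
                r = fx.te_record(te)
                total = r["total"]
                for cell, num in (("shared", r["shared"][0]),
                                  ("paternal_specific", r["paternal_specific"][0]),
                                  ("maternal_specific", r["maternal_specific"][0])):
                    _compare("table3", te, f"{cell.split('_')[0]}_pct",
                             r[cell][1], 100 * num / total, rows)
            totals = fx.records["_totals"]
            for cell in ("total", "shared", "paternal_specific", "maternal_specific"):
                key = {"total": "total", "shared": "shared",
                       "paternal_specific": "paternal_specific",
                       "maternal_specific": "maternal_specific"}[cell]
                summed = sum(fx.te_record(te)[key][0] if key != "total"
                             else fx.te_record(te)["total"] for te in fx.te_families)
                _compare("table3", "_totals", cell, totals[cell], summed, rows)
        else:
            parental = {te: load_paper_fixture("table3").te_record(te)["total"]
                        for te in fx.te_families}
            block = "new" if fid.endswith("new") else "lost"
            for te in fx.te_families:
                r = fx.te_record(te)
                in_all = r["in_all"][0]
                _compare(fid, te, "in_all_pct", r["in_all"][1],
                         100 * in_all / parental[te], rows)
                for taxon, (cnt, pct) in r["per_taxon"].items():
                    den = in_all if block == "new" else parental[te]
                    _compare(fid, te, f"in_{taxon}_pct", pct, 100 * cnt / den, rows)
                for cat, (cnt, pct) in r["categories"].items():
                    _compare(fid, te, f"{cat}_pct", pct, 100 * cnt / in_all, rows)
            allr = fx.records["_all_tes"]
            grand_parental = sum(parental.values())
            grand = allr["in_all"][0]
            summed = sum(fx.te_record(te)["in_all"][0] for te in fx.te_families)
            _compare(fid, "_all_tes", "in_all", grand, summed, rows)
            _compare(fid, "_all_tes", "in_all_pct", allr["in_all"][1],
                     100 * grand / grand_parental, rows)
            for taxon, (cnt, pct) in allr["per_taxon"].items():
                den = grand if block == "new" else grand_parental
                _compare(fid, "_all_tes", f"in_{taxon}_pct", pct,
                         100 * cnt / den, rows)
            for cat, (cnt, pct) in allr["categories"].items():
                _compare(fid, "_all_tes", f"{cat}_pct", pct, 100 * cnt / grand, rows)
            # the printed ANOVA on this block's category proportions; the
            # construction reproduces the printed F to ~0.5% relative and
            # the between-group SS to 3 decimals
            table, _ = table6_anova(block)
            printed = meta["table6"][block]
            _compare(fid, "_anova", "f", printed["f"], table.f, rows,
                     tol=0.005 * printed["f"])
            _compare(fid, "_anova", "ss_between", printed["ss_between"],
                     table.ss_between, rows, tol=5e-4)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Matrix-level runs


def _analyze_matrices(matrices: Mapping[str, MarkerMatrix], scheme: TaxonScheme,
                      cfg: RunConfig, out: Path, log: list[str]) -> dict:
    summaries = {}
    table5_rows = []
    table3_rows = []
    table4_rows = []
    diversity_rows = []
    origin_rows = []
    stat_rows = []
    for fam, m in matrices.items():
        log.append(f"stage classify/score: family {fam} "
                   f"({m.n_loci} loci x {m.n_accessions} accessions)")
        c = score_polyploid_deviation(classify_parental_bands(m, scheme))
        summary = deviation_summary(c)
        summaries[fam] = summary
        p = summary.parental
        table3_rows.append({"te_family": fam, **p})
        table5_rows.append(summary.to_frame())
        for taxon in scheme.polyploids:
            lo = summary.loss_origin[taxon]
            row = {"te_family": fam, "taxon": taxon,
                   "paternal_lost": lo.paternal_lost,
                   "maternal_lost": lo.maternal_lost,
                   "shared_lost": lo.shared_lost,
                   "fraction_paternal": lo.fraction_paternal}
            if lo.attributable:
                res = chisq_ratio_gof((lo.paternal_lost, lo.maternal_lost))
                ci = newcombe_wilson_ci(lo.paternal_lost, lo.attributable,
                                        1 - cfg.alpha)
                row.update({"chi2_1to1": res.statistic,
                            "p_one_sided": res.p_one_sided,
                            "ci_low": ci[0], "ci_high": ci[1]})
            origin_rows.append(row)
        # progenitor-specific band comparison, under both candidate 2x2
        # layouts (the exact construction behind the published statistic
        # is ambiguous, so both are reported)
        layouts = {
            "specific_vs_shared": [[p["paternal_specific"], p["shared"]],
                                   [p["maternal_specific"], p["shared"]]],
            "specific_vs_rest": [[p["paternal_specific"],
                                  p["total"] - p["paternal_specific"]],
                                 [p["maternal_specific"],
                                  p["total"] - p["maternal_specific"]]],
        }
        for layout, t in layouts.items():
            try:
                res = yates_chisq_2x2(t)
            except ValueError:
                continue
            stat_rows.append({"te_family": fam, "test": layout,
                              "statistic": res.statistic,
                              "p_one_sided": res.p_one_sided})
        for taxon in scheme.polyploids:
            prop = summary.deviation_proportion[taxon]
            n_rel = p["total"] + summary.new.per_taxon[taxon]
            k = summary.new.per_taxon[taxon] + summary.lost.per_taxon[taxon]
            ci = newcombe_wilson_ci(k, n_rel, 1 - cfg.alpha) if n_rel else (None, None)
            table4_rows.append({"te_family": fam, "taxon": taxon,
                                "deviation_proportion": prop,
                                "ci_low": ci[0], "ci_high": ci[1],
                                "new_missing_ratio":
                                    summary.new_missing_ratio[taxon]})
        for taxon in scheme.taxa:
            try:
                est = nei_diversity_profile(m, scheme, taxon)
            except Exception as exc:  # single-accession taxa etc.
                log.append(f"stage diversity: {fam}/{taxon} skipped ({exc})")
                continue
            diversity_rows.append({
                "te_family": fam, "taxon": taxon,
                "n_accessions": est.n_accessions, "bands": est.band_count,
                "prop_polymorphic": est.proportion_polymorphic,
                "gene_diversity": est.gene_diversity,
                "gene_diversity_se": est.gene_diversity_se,
            })
        log.append(f"stage network: family {fam}, {cfg.n_bootstrap} bootstraps")
        annotated, filtered = bootstrap_confidence_network(
            m, n_boot=cfg.n_bootstrap, threshold=0.95, seed=cfg.seed)
        write_splits_nexus(annotated, out / f"network_{fam}.nex")
        write_splits_nexus(filtered, out / f"network_{fam}_confidence.nex")
    if stat_rows:
        pvals = [r["p_one_sided"] for r in stat_rows]
        reject, adj = holm_adjust(pvals, cfg.alpha)
        for r, rej, a in zip(stat_rows, reject, adj):
            r["p_holm"] = a
            r["significant"] = bool(rej)
    pd.DataFrame(table3_rows).to_csv(out / "table3_parental_bands.csv", index=False)
    pd.DataFrame(table4_rows).to_csv(out / "table4_deviation_proportions.csv",
                                     index=False)
    pd.concat(table5_rows, ignore_index=True).to_csv(
        out / "table5_deviation_blocks.csv", index=False)
    pd.DataFrame(diversity_rows).to_csv(out / "fig2_diversity.csv", index=False)
    pd.DataFrame(origin_rows).to_csv(out / "fig3_loss_origin.csv", index=False)
    if stat_rows:
        pd.DataFrame(stat_rows).to_csv(out / "table3_tests.csv", index=False)
    # cross-family ANOVA of category proportions (needs a nonzero block per family)
    for block in ("new", "lost"):
        groups = []
        cats = sharing_categories(scheme.polyploids)
        usable = [s for s in summaries.values()
                  if (s.new if block == "new" else s.lost).in_all > 0]
        if len(usable) >= 2:
            for cat in cats:
                groups.append([
                    (s.new if block == "new" else s.lost).categories[cat]
                    / (s.new if block == "new" else s.lost).in_all
                    for s in usable
                ])
            table, _ = oneway_anova_tukey(groups)
            pd.DataFrame([{"block": block, "f": table.f, "p": table.p,
                           "ss_between": table.ss_between,
                           "ss_within": table.ss_within,
                           "df_between": table.df_between,
                           "df_within": table.df_within}]).to_csv(
                out / f"table6_anova_{block}.csv", index=False)
    return summaries


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured end-to-end run; returns the summary objects."""
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"ssapkit {__version__}", f"mode: {cfg.mode}",
                      f"seed: {cfg.seed}", f"alpha: {cfg.alpha}"]
    result: dict = {}
    try:
        if cfg.mode == "fixtures":
            comparison = reproduce_tables()
            comparison.to_csv(out / "observed_vs_printed.csv", index=False)
            for block in ("new", "lost"):
                table, tukey = table6_anova(block)
                pd.DataFrame([{"block": block, "f": table.f, "p": table.p,
                               "ss_between": table.ss_between,
                               "ss_within": table.ss_within}]).to_csv(
                    out / f"table6_anova_{block}.csv", index=False)
            n_bad = int((comparison["match"] == "MISMATCH").sum())
            log.append(f"stage fixtures: {len(comparison)} cells checked, "
                       f"{n_bad} unexplained mismatches")
            result["comparison"] = comparison
        else:
            if cfg.mode == "simulate":
                params = (load_params(cfg.sim_params_path)
                          if cfg.sim_params_path else default_study_params(cfg.seed))
                matrices, scheme, truth = simulate_dataset(params)
                truth.events.to_csv(out / "simulation_events.csv", index=False)
                result["truth"] = truth
                log.append(f"stage simulate: {len(matrices)} families, "
                           f"seed {params.seed}")
            else:
                if not cfg.matrix_paths or not cfg.scheme_path:
                    raise ValueError("matrices mode needs matrix_paths and scheme_path")
                scheme = read_taxon_scheme(cfg.scheme_path)
                matrices = {fam: read_matrix(p, fam)
                            for fam, p in cfg.matrix_paths.items()}
                for fam, p in cfg.matrix_paths.items():
                    digest = sha256(Path(p).read_bytes()).hexdigest()[:16]
                    log.append(f"input {fam}: {p} sha256:{digest}")
            result["summaries"] = _analyze_matrices(matrices, scheme, cfg, out, log)
            result["scheme"] = scheme
    except Exception as exc:
        log.append(f"ABORTED: {type(exc).__name__}: {exc}")
        (out / "run_log.txt").write_text("\n".join(log) + "\n")
        raise
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return result
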
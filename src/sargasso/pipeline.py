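"""End-to-end orchestration: filter → rarefy → α → β → spatial → db-RDA → NCM.

One TOML configuration file drives the whole analysis; each stage writes its
own TSV/JSON artifacts and a top-level ``report.json`` collects the result
classes (α tables and tests, PERMANOVA/PERMDISP/pairwise tables, SIMPER,
distance-decay statistics, the selected db-RDA model, variation-partitioning
fractions and neutral-model fits per stratum).  A single global seed expands
to per-stage seeds by fixed offsets so stages can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from . import alpha, beta, neutral, ordination, spatial
from .table import read_table, rarefy, remove_contaminants, write_table

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

# fixed per-stage seed offsets from the global seed
_SEED_OFFSETS = {"rarefy": 1, "beta": 2, "spatial": 3, "ordination": 4}

ENV_VARIABLES_DEFAULT = [
    "temperature", "salinity", "nitrate", "chla", "sargassum_density", "depth_m",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _write_dm(dm: DistanceMatrix, path: Path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t"
    )


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the full analysis described by ``config`` (dict or TOML path)."""
    if not isinstance(config, dict):
        config = load_config(config)
    inp = config.get("input", {})
    out = Path(outdir or config.get("output", {}).get("dir", "sargasso_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    n_perm = int(config.get("n_permutations", 999))
    flags = config.get("flags", {})
    normalized = bool(flags.get("unifrac_normalized", True))
    center = flags.get("permdisp_center", "centroid")
    env_vars = config.get("environment", {}).get("variables", ENV_VARIABLES_DEFAULT)

    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": seed,
                    "notices": []}

    def stage(name):
        def wrap(fn, *a, **kw):
            try:
                log.info("stage %s", name)
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrap

    # -- load ----------------------------------------------------------
    def _load():
        table = read_table(inp["table"], inp.get("table_format", "tsv"))
        metadata = pd.read_csv(inp["metadata"], sep="\t", index_col=0,
                               keep_default_na=False, na_values=[""])
        metadata = metadata.loc[[s for s in table.sample_ids if s in metadata.index]]
        table = table.select_samples(list(metadata.index))
        tree = None
        if inp.get("tree"):
            tree = TreeNode.read(str(inp["tree"]), convert_underscores=False)
        negctrl = None
        if inp.get("negative_control"):
            negctrl = pd.read_csv(
                inp["negative_control"], sep="\t", index_col=0
            ).iloc[:, 0]
        return table, metadata, tree, negctrl

    table, metadata, tree, negctrl = stage("load")(_load)
    log.info("loaded %d samples x %d OTUs", *table.shape)

    # -- contaminant filter -------------------------------------------
    if negctrl is not None:
        def _filter():
            filtered, rep = remove_contaminants(table, negctrl)
            rep.removed.to_csv(out / "contaminants_removed.tsv", sep="\t", index=False)
            return filtered, rep
        table, rep = stage("contaminant_filter")(_filter)
        report["contaminants_removed"] = list(rep.removed["otu_id"])

    # -- rarefaction ---------------------------------------------------
    def _rarefy():
        depth = int(config.get("rarefaction", {}).get(
            "depth", table.sample_totals().min()))
        t = rarefy(table, depth, seed=seed + _SEED_OFFSETS["rarefy"])
        t = t.drop_empty_otus()
        write_table(t, out / "table_rarefied.tsv")
        return t, depth
    table, depth = stage("rarefaction")(_rarefy)
    metadata = metadata.loc[table.sample_ids]
    report["rarefaction_depth"] = depth
    report["n_samples"] = len(table.sample_ids)
    report["n_otus"] = len(table.otu_ids)

    # -- alpha ---------------------------------------------------------
    def _alpha():
        at = alpha.alpha_table(table)
        at.to_csv(out / "alpha_diversity.tsv", sep="\t")
        tests = []
        for factor in ("depth_category", "region"):
            if factor not in metadata.columns:
                continue
            for metric in at.columns:
                h, df, p = alpha.kruskal_wallis(
                    at[metric].to_numpy(), metadata[factor].to_numpy()
                )
                tests.append({"factor": factor, "metric": metric,
                              "H": h, "df": df, "p": p})
        pd.DataFrame(tests).to_csv(out / "alpha_tests.tsv", sep="\t", index=False)
        return at, tests
    alpha_tab, alpha_tests = stage("alpha")(_alpha)
    report["alpha_tests"] = alpha_tests

    # -- beta ----------------------------------------------------------
    def _beta():
        bc = beta.bray_curtis(table)
        _write_dm(bc, out / "bray_curtis.tsv")
        if tree is not None:
            dm = beta.weighted_unifrac(table, tree, normalized=normalized)
            _write_dm(dm, out / "weighted_unifrac.tsv")
            primary = "weighted_unifrac"
        else:
            dm = bc
            primary = "bray_curtis"
            report["notices"].append(
                "no tree supplied: beta-diversity restricted to Bray-Curtis"
            )
        pc = beta.pcoa(dm)
        k = min(5, pc.coordinates.shape[1])
        coords = pd.DataFrame(
            pc.coordinates[:, :k], index=pc.ids,
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        return dm, primary
    dm, primary_metric = stage("beta")(_beta)
    report["primary_distance"] = primary_metric

    def _tests():
        res = {}
        bseed = seed + _SEED_OFFSETS["beta"]
        for factor in ("region", "depth_category"):
            if factor not in metadata.columns:
                continue
            g = metadata[factor]
            pr = beta.permanova(dm, g, n_perm=n_perm, seed=bseed)
            entry = {"pseudo_F": pr.pseudo_F, "p": pr.p,
                     "ss_among": pr.ss_among, "ss_within": pr.ss_within,
                     "ss_total": pr.ss_total}
            r, p_an = beta.anosim(dm, g, n_perm=n_perm, seed=bseed)
            entry["anosim_R"], entry["anosim_p"] = r, p_an
            if (g.value_counts() >= 2).all():
                pdres = beta.permdisp(dm, g, n_perm=n_perm, seed=bseed, center=center)
                entry["permdisp_F"], entry["permdisp_p"] = pdres.F, pdres.p
            if pr.p <= 0.05 and g.nunique() > 2:
                pw = beta.pairwise_permanova(dm, g, n_perm=n_perm, seed=bseed)
                pw.to_csv(out / f"pairwise_permanova_{factor}.tsv",
                          sep="\t", index=False)
                entry["pairwise"] = pw.to_dict(orient="records")
            res[factor] = entry
        if "region" in metadata.columns:
            crossed = metadata.get("depth_category")
            sims = beta.simper(table, metadata["region"], crossed)
            rows = [
                {"group_1": s.group_1, "group_2": s.group_2,
                 "overall_dissimilarity_pct": s.overall_dissimilarity,
                 "n_pairs": s.n_pairs}
                for s in sims
            ]
            pd.DataFrame(rows).to_csv(out / "simper_summary.tsv",
                                      sep="\t", index=False)
            res["simper"] = rows
        return res
    report["beta_tests"] = stage("beta_tests")(_tests)

    # -- spatial -------------------------------------------------------
    def _spatial():
        geo = spatial.haversine_matrix(metadata)
        _write_dm(geo, out / "geographic_km.tsv")
        res = {}
        sseed = seed + _SEED_OFFSETS["spatial"]
        dd = beta.distance_decay(dm, geo)
        res["distance_decay"] = {"all": vars(dd) | {"df": list(dd.df)}}
        if "depth_category" in metadata.columns:
            for stratum in metadata["depth_category"].unique():
                ids = list(metadata.index[metadata["depth_category"] == stratum])
                if len(ids) >= 3:
                    ddx = beta.distance_decay(dm.filter(ids), geo.filter(ids))
                    res["distance_decay"][str(stratum)] = vars(ddx) | {
                        "df": list(ddx.df)}
        if "temperature" in metadata.columns:
            tdm = DistanceMatrix(
                np.abs(metadata["temperature"].to_numpy()[:, None]
                       - metadata["temperature"].to_numpy()[None, :]),
                list(metadata.index),
            )
            r, p = spatial.mantel(tdm, geo, n_perm=n_perm, seed=sseed)
            res["mantel_temperature_geography"] = {"r": r, "r_squared": r ** 2,
                                                   "p": p}
        r, p = spatial.mantel(dm, geo, n_perm=n_perm, seed=sseed)
        res["mantel_community_geography"] = {"r": r, "r_squared": r ** 2, "p": p}
        basis = spatial.pcnm(geo)
        basis.as_dataframe().to_csv(out / "pcnm_eigenfunctions.tsv", sep="\t")
        res["pcnm"] = {"n_axes": basis.eigenfunctions.shape[1],
                       "threshold_km": basis.threshold}
        return geo, basis, res
    geo, basis, spatial_res = stage("spatial")(_spatial)
    report["spatial"] = spatial_res

    # -- constrained ordination ---------------------------------------
    def _ordination():
        env = metadata[[v for v in env_vars if v in metadata.columns]]
        S = basis.as_dataframe()
        oseed = seed + _SEED_OFFSETS["ordination"]
        selected, steps = ordination.forward_select(
            dm, env, Z=S, n_perm=n_perm, seed=oseed
        )
        steps.to_csv(out / "forward_selection.tsv", sep="\t", index=False)
        res = {"selected_variables": selected}
        if selected:
            model = ordination.dbrda(dm, env[selected], Z=S,
                                     n_perm=n_perm, seed=oseed)
            res["model"] = {
                "pseudo_F": model.pseudo_F, "p": model.p,
                "r_squared": model.r_squared,
                "adj_r_squared": model.adj_r_squared,
                "df": [model.m, model.n - model.m - model.q - 1],
            }
        vp = ordination.variation_partition(dm, env, S, n_perm=n_perm, seed=oseed)
        res["variation_partition"] = {
            "a_pure_environment": vp.a, "b_shared": vp.b,
            "c_pure_space": vp.c, "d_residual": vp.d,
            "apportioned": vp.apportioned,
            "environmental_fraction": vp.environmental_fraction,
            "spatial_fraction": vp.spatial_fraction,
            "adj_r_squared_combined": vp.adj_combined,
        }
        return res
    report["ordination"] = stage("ordination")(_ordination)

    # -- neutral model -------------------------------------------------
    def _ncm():
        res = {}
        strata = ["all"]
        if "depth_category" in metadata.columns:
            strata += [str(s) for s in metadata["depth_category"].unique()]
        for stratum in strata:
            try:
                fit = neutral.ncm_by_stratum(table, metadata, stratum)
            except ValueError as exc:
                report["notices"].append(f"NCM skipped for {stratum!r}: {exc}")
                continue
            fit.taxa.to_csv(out / f"ncm_taxa_{stratum}.tsv", sep="\t")
            res[stratum] = fit.summary()
        return res
    report["ncm"] = stage("ncm")(_ncm)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
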
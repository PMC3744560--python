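"""End-to-end self-verified analysis pipeline.

Runs the full duplication-verified workflow on a dataset (real or
simulated): normalization -> residuals -> reference group -> above-background
count N -> hypervariable selection per duplicate (intersected) -> profile
reproducibility filter -> baseline differential expression with jackknife ->
clustering per group (co-clustering intersected across duplicates) ->
correlation mosaics -> duplicated partial-correlation networks merged with
group provenance.  Every stage writes a plain-text artifact and the manifest
records counts, thresholds, seed and a checksum per file, so an identical
rerun is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import synthetic
from .datasets import ExpressionDataset, GROUPS, profile_matrix, read_dataset
from .normalization import (
    compute_residuals,
    identify_background_cohort,
    identify_equally_expressed_cohort,
    normalize_arrays,
)
from .selection import (
    associative_de_test,
    build_reference_group,
    jackknife_reproducibility,
    make_de_selector,
    profile_reproducibility_filter,
    select_above_background,
    select_hve,
)
from .clustering import build_mosaic, correlation_cluster
from .network import ThresholdSet, build_network, edges_to_frame

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    matrix_path: str | None = None
    metadata_path: str | None = None
    simulation: synthetic.SimulationConfig | None = None
    out_dir: str = "pathdyn_out"
    cc_min: float = 0.8
    thresholds: ThresholdSet = field(default_factory=ThresholdSet.duplicated)
    alpha: float = 0.05
    fold_cutoff: float = 2.0
    min_expression: float = 20.0
    seed: int = 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label="gene_id") -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", index_label=index_label)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "thresholds": {
            "cc_min": cfg.cc_min,
            "t_e": cfg.thresholds.t_e,
            "t_m": cfg.thresholds.t_m,
            "t_a": cfg.thresholds.t_a,
            "alpha": cfg.alpha,
            "fold_cutoff": cfg.fold_cutoff,
            "min_expression": cfg.min_expression,
        },
        "stages": {},
        "files": {},
    }

    def record(stage: str, path: Path | None = None, **info) -> None:
        manifest["stages"][stage] = info
        if path is not None:
            manifest["files"][str(path.relative_to(out))] = _sha256(path)

    def fail(stage: str, err: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # stage 1: input
    try:
        if cfg.simulation is not None:
            ds, truth = synthetic.generate_dataset(cfg.simulation)
            synthetic.write_simulation(ds, truth, out)
        elif cfg.matrix_path and cfg.metadata_path:
            ds = read_dataset(cfg.matrix_path, cfg.metadata_path)
        else:
            raise ValueError("provide matrix/metadata paths or a simulation config")
    except Exception as e:  # noqa: BLE001 - stage name must propagate
        fail("input", e)
    record("input", n_genes=ds.n_genes, n_arrays=len(ds.array_ids))

    # stage 2: normalization
    try:
        bg = identify_background_cohort(ds)
        cohort = identify_equally_expressed_cohort(ds, bg)
        nm = normalize_arrays(ds, cohort)
    except Exception as e:
        fail("normalization", e)
    p = out / "normalized.tsv"
    _write_tsv(nm.values, p)
    report = {
        "background_cohort_size": len(bg.member_genes),
        "mu_bg": bg.mu_bg,
        "sigma_bg": bg.sigma_bg,
        "ks_p_background": bg.ks_p,
        "equally_expressed_cohort_size": len(cohort),
        "per_array": nm.scaling.to_dict(orient="index"),
    }
    (out / "normalization_report.json").write_text(json.dumps(report, indent=1))
    record("normalization", p, **{k: v for k, v in report.items() if k != "per_array"})
    manifest["files"]["normalization_report.json"] = _sha256(
        out / "normalization_report.json"
    )

    # stage 3: residuals
    try:
        rm = compute_residuals(nm)
    except Exception as e:
        fail("residuals", e)
    p = out / "residuals.tsv"
    _write_tsv(rm.values, p)
    record("residuals", p, ks_p_global=rm.ks_p_global)

    # stage 4: above background + reference group
    try:
        above, N, by_group = select_above_background(
            nm, bg, alpha=cfg.alpha, per_group=True
        )
        ref = build_reference_group(rm, above, alpha=cfg.alpha)
    except Exception as e:
        fail("reference_group", e)
    record(
        "reference_group",
        n_above_background=N,
        reference_members=len(ref.member_genes),
        pooled_variance=ref.pooled_variance,
    )

    # stage 5: HVE selection per group on per-line normalized profiles
    # (temporal variability), intersected across duplicates
    try:
        hve_by_group: dict[str, set] = {}
        hve_tables = []
        for grp in sorted(set(rm.meta["group"])):
            dup_sets = []
            for dup in sorted(set(rm.meta[rm.meta["group"] == grp]["duplicate_idx"])):
                cols = rm.columns_for(group=grp, duplicate=dup)
                tab = select_hve(nm.values, ref, N, columns=cols, genes=above)
                tab["group"], tab["duplicate"] = grp, dup
                hve_tables.append(tab)
                dup_sets.append(set(tab.index[tab["selected"]]))
            hve_by_group[grp] = set.intersection(*dup_sets) if dup_sets else set()
        hve = sorted(set().union(*hve_by_group.values()))
    except Exception as e:
        fail("hve_selection", e)
    p = out / "hve.tsv"
    _write_tsv(pd.concat(hve_tables), p)
    record(
        "hve_selection",
        p,
        n_hve=len(hve),
        **{f"n_hve_{g}": len(s) for g, s in hve_by_group.items()},
    )

    # stage 6: profile reproducibility filter
    try:
        pairs = {}
        for grp in sorted(set(rm.meta["group"])):
            dups = sorted(set(rm.meta[rm.meta["group"] == grp]["duplicate_idx"]))
            prof = [
                profile_matrix(nm.values.loc[hve], rm.meta, grp, d) for d in dups[:2]
            ]
            pairs[grp] = (prof[0], prof[1])
        reproducible = profile_reproducibility_filter(pairs, cc_min=cfg.cc_min)
    except Exception as e:
        fail("profile_reproducibility", e)
    record("profile_reproducibility", n_reproducible=len(reproducible))

    # stage 7: baseline differential expression + jackknife
    try:
        t0 = min(rm.meta["timepoint_h"])
        case_cols = rm.columns_for(group="case", timepoint=t0)
        ctrl_cols = rm.columns_for(group="control", timepoint=t0)
        case_res, ctrl_res = rm.values[case_cols], rm.values[ctrl_cols]
        lin = nm.values.apply(lambda c: 2.0**c)
        de = associative_de_test(
            case_res,
            ctrl_res,
            ref,
            N,
            alpha=cfg.alpha,
            case_above=by_group.get("case", set()),
            control_above=by_group.get("control", set()),
            case_expression=lin[case_cols].mean(axis=1),
            control_expression=lin[ctrl_cols].mean(axis=1),
            min_expression=cfg.min_expression,
            fold_cutoff=cfg.fold_cutoff,
        )
        if len(case_cols) >= 2 and len(ctrl_cols) >= 2:
            de["jackknife_pct"] = jackknife_reproducibility(
                case_res, ctrl_res, make_de_selector(ref, N, alpha=cfg.alpha)
            )
    except Exception as e:
        fail("differential_expression", e)
    p = out / "differential_expression.tsv"
    _write_tsv(de, p)
    record("differential_expression", p, n_de=int(de["de"].sum()))

    # stage 8: clustering per group, co-clustering verified across duplicates
    try:
        cluster_sets, mosaics = {}, {}
        co_clustered: dict[str, set] = {}
        for grp in sorted(set(rm.meta["group"])):
            dups = sorted(set(rm.meta[rm.meta["group"] == grp]["duplicate_idx"]))
            per_dup = []
            for d in dups[:2]:
                prof = profile_matrix(nm.values.loc[reproducible], rm.meta, grp, d)
                per_dup.append(correlation_cluster(prof, cfg.cc_min))
            pair_sets = []
            for cs in per_dup:
                pairs_ = set()
                for cl in cs.clusters:
                    ms = cl.members
                    pairs_.update(
                        (a, b) for ia, a in enumerate(ms) for b in ms[ia + 1:]
                    )
                pair_sets.append(pairs_)
            verified_pairs = set.intersection(*pair_sets) if pair_sets else set()
            co_clustered[grp] = {g for pr in verified_pairs for g in pr}
            cluster_sets[grp] = per_dup[0]
        genes_kept = sorted(set().union(*co_clustered.values()))
    except Exception as e:
        fail("clustering", e)
    rows = []
    for grp, cs in cluster_sets.items():
        for ci, cl in enumerate(cs.clusters):
            for g in cl.members:
                rows.append(
                    {
                        "group": grp,
                        "cluster": ci,
                        "gene_id": g,
                        "seed": cl.seed,
                        "connectivity": int(cs.connectivity.get(g, 0)),
                        "co_clustered_verified": g in co_clustered[grp],
                    }
                )
    p = out / "clusters.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    record("clustering", p, n_co_clustered=len(genes_kept))

    # stage 9: correlation mosaics (control ordering reused for case)
    try:
        ref_grp = "control" if "control" in cluster_sets else sorted(cluster_sets)[0]
        order = None
        for grp in [ref_grp] + [g for g in sorted(cluster_sets) if g != ref_grp]:
            prof = profile_matrix(
                nm.values.loc[reproducible], rm.meta, grp,
                sorted(set(rm.meta[rm.meta["group"] == grp]["duplicate_idx"]))[0],
            )
            if order is None:
                mosaic = build_mosaic(cluster_sets[grp], prof, grp)
                order, bounds = mosaic.ordered_genes, mosaic.cluster_boundaries
            else:
                mosaic = build_mosaic(cluster_sets[grp], prof, grp, order, bounds)
            mosaics[grp] = mosaic
            mp = out / f"mosaic_{grp}.tsv"
            _write_tsv(mosaic.corr, mp)
            manifest["files"][mp.name] = _sha256(mp)
    except Exception as e:
        fail("mosaic", e)
    record("mosaic", n_ordered_genes=len(order or []))

    # stage 10: duplicated partial-correlation network with provenance
    try:
        net_genes = genes_kept if len(genes_kept) >= 2 else reproducible
        experiments = {}
        for grp in sorted(set(rm.meta["group"])):
            dups = sorted(set(rm.meta[rm.meta["group"] == grp]["duplicate_idx"]))
            experiments[grp] = [
                profile_matrix(nm.values.loc[net_genes], rm.meta, grp, d)
                for d in dups
            ]
        edges = build_network(experiments, cfg.thresholds)
    except Exception as e:
        fail("network", e)
    p = out / "network_edges.tsv"
    edges_to_frame(edges).to_csv(p, sep="\t", index=False)
    record("network", p, n_edges=len(edges))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
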
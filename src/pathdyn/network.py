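"""Partial-correlation gene network inference with duplication filtering.

For a candidate gene pair (X, Y) correlated above the environment threshold
t_e, the first-order partial correlation

    pr_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) * (1 - r_yz^2))

is computed for every conditioning gene Z in the pair's environment.  The
row of |pr| values is summarised by its minimum PC_m and mean PC_a; the pair
is an *essential* (direct) association when PC_m >= t_m and PC_a >= t_a.  A
single row entry below t_m (a "hole" at Z) marks the association as indirect
via Z -- unless the (X, Z) row has the reciprocal hole at Y, in which case
X, Y, Z form a triangle of mutual associations.  Edges are reported only
when they reproduce across all duplicated experiments of a phenotype group,
with the group provenance (control-only / case-only / both) retained.

Thresholds are calibrated by Monte Carlo on randomized null data; the
defaults reproduce the study design: (0.8, 0.6, 0.8) for a single
experiment and (0.6, 0.4, 0.4) under duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import generate_randomized_replicates

log = logging.getLogger(__name__)

# conditioning genes this close to |r| = 1 carry no usable information
_R_LIMIT = 1.0 - 1e-9


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdSet:
    """Environment (t_e), minimum (t_m) and average (t_a) thresholds."""

    t_e: float
    t_m: float
    t_a: float

    def __post_init__(self):
        for name in ("t_e", "t_m", "t_a"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise NetworkError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def single(cls) -> "ThresholdSet":
        return cls(0.8, 0.6, 0.8)

    @classmethod
    def duplicated(cls) -> "ThresholdSet":
        return cls(0.6, 0.4, 0.4)


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of X and Y given Z (exact formula)."""
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise NetworkError("partial correlation undefined: |conditioning r| >= 1")
    return (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))


def select_environment(x, corr: pd.DataFrame, t_e: float) -> list:
    """E_x: all genes whose |correlation| with x reaches t_e (x excluded)."""
    row = corr.loc[x].drop(index=x)
    return list(row.index[row.abs() >= t_e])


@dataclass
class PartialCorrelationRow:
    x: str
    y: str
    r_xy: float
    entries: dict  # z -> signed pr_xy.z
    pc_m: float  # min |entry| (|r_xy| when the row is empty)
    pc_a: float  # mean |entry| (|r_xy| when the row is empty)
    holes: list  # z with |entry| < t_m
    t_m: float


def _row_from_corr(
    corr: pd.DataFrame, x, y, cond: list, t_m: float
) -> PartialCorrelationRow:
    r_xy = float(corr.loc[x, y])
    usable = []
    for z in cond:
        if z in (x, y):
            continue
        if abs(corr.loc[x, z]) >= _R_LIMIT or abs(corr.loc[y, z]) >= _R_LIMIT:
            log.debug("dropping degenerate conditioner %s for pair (%s, %s)", z, x, y)
            continue
        usable.append(z)
    if not usable:
        pc = abs(r_xy)
        return PartialCorrelationRow(x, y, r_xy, {}, pc, pc, [], t_m)
    r_xz = corr.loc[x, usable].to_numpy(dtype=float)
    r_yz = corr.loc[y, usable].to_numpy(dtype=float)
    pr = (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    entries = dict(zip(usable, pr))
    abs_pr = np.abs(pr)
    holes = [z for z, v in entries.items() if abs(v) < t_m]
    return PartialCorrelationRow(
        x, y, r_xy, entries, float(abs_pr.min()), float(abs_pr.mean()), holes, t_m
    )


def partial_correlation_row(
    x, y, env, profiles: pd.DataFrame, *, t_m: float = 0.6
) -> PartialCorrelationRow:
    """Row of partial correlations of pair (x, y) over its environment.

    ``profiles`` is a genes x samples matrix; correlations are Pearson over
    the shared sampling points.  With an empty conditioning set the raw
    |r_xy| stands in for both PC statistics.
    """
    needed = sorted({x, y} | set(env))
    sub = profiles.loc[needed].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    for g, s in zip(needed, sd):
        if s <= 1e-300:
            raise NetworkError(f"constant profile for gene {g!r}")
    corr = pd.DataFrame(np.corrcoef(sub), index=needed, columns=needed)
    cond = [z for z in env if z not in (x, y)]
    return _row_from_corr(corr, x, y, cond, t_m)


@dataclass
class Classification:
    kind: str  # "essential" | "indirect" | "triangle" | "none"
    via: str | None = None

    @property
    def keeps_edge(self) -> bool:
        return self.kind in ("essential", "triangle")


def classify_edge(
    row_xy: PartialCorrelationRow, hole_rows: dict, ts: ThresholdSet
) -> Classification:
    """Essential / indirect-via-Z / triangle decision for one pair.

    ``hole_rows`` maps each hole gene z to the row for the pair (x, z); it
    is consulted for the reciprocal hole that distinguishes a triangle from
    a plain indirect association.
    """
    if row_xy.pc_m >= ts.t_m and row_xy.pc_a >= ts.t_a:
        return Classification("essential")
    if len(row_xy.holes) == 1:
        z = row_xy.holes[0]
        row_xz = hole_rows.get(z)
        if row_xz is not None and row_xy.y in row_xz.holes:
            return Classification("triangle", via=z)
        return Classification("indirect", via=z)
    return Classification("none")


def evaluate_experiment(profiles: pd.DataFrame, ts: ThresholdSet) -> dict:
    """Classify every candidate pair of one experiment.

    Candidates are unordered pairs with |r| >= t_e.  The conditioning set of
    a pair is the union of the two genes' environments (a symmetric reading
    of the per-gene environment).  Returns
    ``{(x, y): (Classification, r_xy)}`` with x < y in input order.
    """
    genes = list(profiles.index)
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    keep_mask = sd > 1e-300
    keep = [g for g, ok in zip(genes, keep_mask) if ok]
    if len(keep) < 2:
        return {}
    if len(keep) < len(genes):
        log.debug("%d constant profiles skipped in evaluation", len(genes) - len(keep))
    A = np.corrcoef(X[keep_mask])
    absA = np.abs(A)
    n = len(keep)
    env_mask = absA >= ts.t_e  # env_mask[i, j]: j in E_i (diag true, masked later)
    np.fill_diagonal(env_mask, False)
    results: dict = {}
    row_cache: dict = {}

    def get_row(i: int, j: int) -> PartialCorrelationRow:
        key = (i, j)
        row = row_cache.get(key)
        if row is None:
            cond = env_mask[i] | env_mask[j]
            cond[i] = cond[j] = False
            # drop conditioners indistinguishable from x or y (|r| ~ 1)
            cond &= (absA[i] < _R_LIMIT) & (absA[j] < _R_LIMIT)
            zi = np.nonzero(cond)[0]
            r_xy = float(A[i, j])
            if zi.size == 0:
                pc = abs(r_xy)
                row = PartialCorrelationRow(
                    keep[i], keep[j], r_xy, {}, pc, pc, [], ts.t_m
                )
            else:
                r_xz, r_yz = A[i, zi], A[j, zi]
                pr = (r_xy - r_xz * r_yz) / np.sqrt(
                    (1.0 - r_xz**2) * (1.0 - r_yz**2)
                )
                abs_pr = np.abs(pr)
                holes = [keep[z] for z in zi[abs_pr < ts.t_m]]
                row = PartialCorrelationRow(
                    keep[i],
                    keep[j],
                    r_xy,
                    {keep[z]: float(v) for z, v in zip(zi, pr)},
                    float(abs_pr.min()),
                    float(abs_pr.mean()),
                    holes,
                    ts.t_m,
                )
            row_cache[key] = row
        return row

    gene_pos = {g: i for i, g in enumerate(keep)}
    iu, ju = np.triu_indices(n, k=1)
    cand = absA[iu, ju] >= ts.t_e
    for i, j in zip(iu[cand], ju[cand]):
        row = get_row(int(i), int(j))
        hole_rows = (
            {z: get_row(int(i), gene_pos[z]) for z in row.holes}
            if len(row.holes) == 1
            else {}
        )
        results[(keep[i], keep[j])] = (classify_edge(row, hole_rows, ts), row.r_xy)
    return results


@dataclass
class NetworkEdge:
    x: str
    y: str
    sign: int
    classification: str  # classification kind in the duplicate experiments
    provenance: str  # "control_only" | "case_only" | "both"
    pc_stats: dict = field(default_factory=dict)  # (group, dup) -> (pc_m, pc_a)


def _group_edges(duplicate_results: list) -> dict:
    """Pairs kept (essential/triangle) in every duplicate with agreeing sign."""
    kept: dict = {}
    common = set(duplicate_results[0])
    for res in duplicate_results[1:]:
        common &= set(res)
    for pair in common:
        classes = [res[pair][0] for res in duplicate_results]
        if not all(c.keeps_edge for c in classes):
            continue
        signs = {1 if res[pair][1] >= 0 else -1 for res in duplicate_results}
        if len(signs) > 1:
            log.info("pair %s dropped: sign disagrees across duplicates", pair)
            continue
        kind = (
            "triangle" if any(c.kind == "triangle" for c in classes) else "essential"
        )
        kept[pair] = (signs.pop(), kind)
    return kept


def build_network(experiments: dict, ts: ThresholdSet) -> list:
    """Duplication-verified edges with group provenance.

    ``experiments`` maps group name -> list of genes x samples profile
    DataFrames (>= 2 duplicated experiments each, identical gene universe).
    An edge is reported when it is kept in ALL duplicates of at least one
    group and its correlation sign agrees across those duplicates.
    """
    universes = {
        tuple(p.index) for profs in experiments.values() for p in profs
    }
    if len(universes) > 1:
        raise NetworkError("inconsistent gene universes between duplicates")
    per_group: dict = {}
    for group, profs in experiments.items():
        if len(profs) < 2:
            raise NetworkError(f"group {group!r} needs >= 2 duplicate experiments")
        per_group[group] = _group_edges([evaluate_experiment(p, ts) for p in profs])
    edges = []
    all_pairs = set().union(*per_group.values()) if per_group else set()
    for pair in sorted(all_pairs):
        groups = [g for g, kept in per_group.items() if pair in kept]
        signs = {per_group[g][pair][0] for g in groups}
        if len(signs) > 1:
            log.info("pair %s dropped: sign disagrees between groups", pair)
            continue
        kinds = {per_group[g][pair][1] for g in groups}
        provenance = "both" if len(groups) == 2 else f"{groups[0]}_only"
        edges.append(
            NetworkEdge(
                x=pair[0],
                y=pair[1],
                sign=signs.pop(),
                classification="triangle" if "triangle" in kinds else "essential",
                provenance=provenance,
            )
        )
    return edges


def edges_to_frame(edges: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x": e.x,
                "y": e.y,
                "sign": e.sign,
                "classification": e.classification,
                "provenance": e.provenance,
            }
            for e in edges
        ],
        columns=["x", "y", "sign", "classification", "provenance"],
    )


def to_networkx(edges: list):
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_edge(
            e.x, e.y, sign=e.sign, classification=e.classification,
            provenance=e.provenance,
        )
    return g


def write_sif(edges: list, path) -> None:
    with open(path, "w") as fh:
        for e in edges:
            rel = "pos" if e.sign > 0 else "neg"
            fh.write(f"{e.x}\t{rel}\t{e.y}\n")


@dataclass
class CalibrationResult:
    fp_rate: float  # mean per-simulation proportion of evaluated pairs kept
    fp_rate_pooled: float  # total kept / total evaluated
    fp_rate_all_pairs: float  # total kept / (n_sims * n_genes choose 2)
    n_pairs_evaluated: int
    n_edges: int
    per_sim: list


def calibrate_thresholds(
    n_genes: int,
    n_reps: int,
    ts: ThresholdSet,
    n_sims: int,
    duplicated: bool,
    seed: int,
) -> CalibrationResult:
    """Monte-Carlo false-positive rate of the edge pipeline on null data.

    Each simulation draws i.i.d. standard-normal replicates (two independent
    draws under the duplicated design).  Evaluated pairs are those entering
    environment testing (|r| >= t_e, in every duplicate); ``fp_rate`` is the
    proportion of evaluated pairs reported as edges, averaged over
    simulations with at least one evaluated pair.  ``fp_rate_all_pairs``
    normalises instead by every gene pair in the matrix -- the two
    defensible readings of a false-positive "selection" rate on null data.
    """
    if n_sims < 1:
        raise NetworkError("n_sims must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_sims)]
    gene_ids = [f"g{i}" for i in range(n_genes)]
    per_sim = []
    total_eval = total_kept = 0
    for s in range(n_sims):
        reps = 2 if duplicated else 1
        results = []
        for d in range(reps):
            data = generate_randomized_replicates(
                n_genes, n_reps, child_seeds[2 * s + d]
            )
            prof = pd.DataFrame(data, index=gene_ids)
            results.append(evaluate_experiment(prof, ts))
        evaluated = set(results[0])
        for res in results[1:]:
            evaluated &= set(res)
        kept = _group_edges(results) if duplicated else {
            p: (1 if results[0][p][1] >= 0 else -1, results[0][p][0].kind)
            for p in results[0]
            if results[0][p][0].keeps_edge
        }
        n_eval, n_kept = len(evaluated), len(kept)
        total_eval += n_eval
        total_kept += n_kept
        if n_eval:
            per_sim.append(n_kept / n_eval)
    fp = float(np.mean(per_sim)) if per_sim else 0.0
    pooled = total_kept / total_eval if total_eval else 0.0
    n_pairs_total = n_sims * n_genes * (n_genes - 1) // 2
    return CalibrationResult(
        fp_rate=fp,
        fp_rate_pooled=pooled,
        fp_rate_all_pairs=total_kept / n_pairs_total,
        n_pairs_evaluated=total_eval,
        n_edges=total_kept,
        per_sim=per_sim,
    )
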
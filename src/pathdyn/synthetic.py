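"""Synthetic duplicated time-course expression data with known ground truth.

The generator emulates a two-group (case/control) stimulation time course
measured on expression arrays: a low-intensity background mode, a large
stable equally-expressed cohort, hypervariable genes organised in peak-time
clusters, planted direct and mediated (chain) gene-gene couplings, genes with
group-specific behaviour, per-array distortions, and duplicated independent
experiments (one cell line per duplicate).  Everything is generated on the
log2 scale and exponentiated, so intensities are strictly positive.

A companion :class:`SyntheticTruth` records which genes play which role so
that selection, clustering and network-inference results can be scored
against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GROUPS, write_dataset

__all__ = [
    "ClusterSpec",
    "EdgeSpec",
    "ChainSpec",
    "GroupEffect",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_randomized_replicates",
    "default_config",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates an invariant."""


@dataclass(frozen=True)
class ClusterSpec:
    """A co-expressed gene cluster peaking at ``peak_time_h`` hours."""

    peak_time_h: float
    n_genes: int
    amplitude: float


@dataclass(frozen=True)
class EdgeSpec:
    """A planted direct coupling: gene ``target`` follows gene ``source``.

    ``group`` restricts the coupling to one phenotype group ("case" or
    "control"); with ``group="both"`` the coupling is shared.  In a group
    where the coupling is absent the target gene stays at a flat baseline.
    """

    source: int
    target: int
    sign: int = 1
    group: str = "both"


@dataclass(frozen=True)
class ChainSpec:
    """A mediated association x -> z -> y with no direct x--y term."""

    x: int
    z: int
    y: int


@dataclass(frozen=True)
class GroupEffect:
    """A per-gene phenotype-group difference.

    kind:
        ``constitutive_offset`` -- additive log2 offset in ``group`` at every
        timepoint (a baseline, t=0 difference);
        ``profile_change``     -- the gene follows a different dynamic shape
        in ``group``;
        ``group_unique_dynamic`` -- dynamic in ``group`` only, flat otherwise.
    """

    gene: int
    kind: str
    magnitude: float
    group: str = "case"


_EFFECT_KINDS = {"constitutive_offset", "profile_change", "group_unique_dynamic"}

DEFAULT_TIMEPOINTS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0)


@dataclass
class SimulationConfig:
    n_genes: int = 1000
    n_background: int = 300
    n_stable: int = 400
    cluster_specs: list = field(
        default_factory=lambda: [
            ClusterSpec(0.5, 20, 2.5),
            ClusterSpec(2.0, 20, 2.5),
            ClusterSpec(8.0, 20, 2.5),
            ClusterSpec(24.0, 20, 2.5),
        ]
    )
    timepoints_hours: tuple = DEFAULT_TIMEPOINTS
    lines_per_group: int = 2
    planted_edges: list = field(default_factory=list)
    planted_chains: list = field(default_factory=list)
    group_effects: list = field(default_factory=list)
    # log2-scale magnitudes
    mu_background: float = 6.0
    sigma_background: float = 0.35
    structure_amplitude: float = 2.0
    link_noise_sd: float = 0.3
    array_scale_sd: float = 0.03
    array_offset_sd: float = 0.2
    noise_sd: float = 0.15
    seed: int = 0

    # -- derived index ranges -------------------------------------------
    @property
    def background_idx(self) -> range:
        return range(0, self.n_background)

    @property
    def stable_idx(self) -> range:
        return range(self.n_background, self.n_background + self.n_stable)

    def cluster_idx(self) -> list[range]:
        out, start = [], self.n_background + self.n_stable
        for spec in self.cluster_specs:
            out.append(range(start, start + spec.n_genes))
            start += spec.n_genes
        return out

    @property
    def free_idx(self) -> range:
        start = self.n_background + self.n_stable + sum(
            s.n_genes for s in self.cluster_specs
        )
        return range(start, self.n_genes)

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        for name in ("n_background", "n_stable", "lines_per_group"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.lines_per_group < 2:
            raise ConfigError(
                "lines_per_group must be >= 2: duplication is required downstream"
            )
        total = self.n_background + self.n_stable + sum(
            s.n_genes for s in self.cluster_specs
        )
        if total > self.n_genes:
            raise ConfigError(
                f"n_background + n_stable + cluster genes ({total}) exceeds n_genes"
            )
        tp = np.asarray(self.timepoints_hours, dtype=float)
        if len(tp) < 3 or not (np.diff(tp) > 0).all():
            raise ConfigError("timepoints_hours must be >= 3 strictly increasing values")
        for spec in self.cluster_specs:
            if spec.n_genes <= 0 or spec.amplitude <= 0:
                raise ConfigError(f"invalid cluster spec {spec}")
            if spec.peak_time_h not in set(tp):
                raise ConfigError(
                    f"cluster peak_time_h {spec.peak_time_h} not among timepoints"
                )
        for v in ("array_scale_sd", "array_offset_sd", "noise_sd", "link_noise_sd"):
            if getattr(self, v) < 0:
                raise ConfigError(f"{v} must be non-negative")
        free = set(self.free_idx)
        for e in self.planted_edges:
            if e.source == e.target:
                raise ConfigError(f"planted_edges: endpoints must differ ({e})")
            for g in (e.source, e.target):
                if not 0 <= g < self.n_genes:
                    raise ConfigError(f"planted_edges: gene index {g} out of range")
                if g not in free:
                    raise ConfigError(
                        f"planted_edges: gene {g} must lie in the free index range"
                    )
            if e.sign not in (-1, 1):
                raise ConfigError(f"planted_edges: sign must be +-1 ({e})")
            if e.group not in GROUPS + ("both",):
                raise ConfigError(f"planted_edges: unknown group {e.group!r}")
        for c in self.planted_chains:
            ids = (c.x, c.z, c.y)
            if len(set(ids)) != 3:
                raise ConfigError(f"planted_chains: x, z, y must be distinct ({c})")
            for g in ids:
                if g not in free:
                    raise ConfigError(
                        f"planted_chains: gene {g} must lie in the free index range"
                    )
        for ge in self.group_effects:
            if ge.kind not in _EFFECT_KINDS:
                raise ConfigError(f"group_effects: unknown kind {ge.kind!r}")
            if not 0 <= ge.gene < self.n_genes:
                raise ConfigError(f"group_effects: gene index {ge.gene} out of range")
            if ge.gene in self.background_idx:
                raise ConfigError("group_effects: cannot target a background gene")
            if ge.group not in GROUPS:
                raise ConfigError(f"group_effects: unknown group {ge.group!r}")
        # structure genes must not collide
        used: set[int] = set()
        for e in self.planted_edges:
            for g in (e.source, e.target):
                if g in used and g != e.source:
                    raise ConfigError(f"gene {g} used by more than one planted structure")
                used.add(g)
        for c in self.planted_chains:
            for g in (c.x, c.z, c.y):
                if g in used:
                    raise ConfigError(f"gene {g} used by more than one planted structure")
                used.add(g)


@dataclass
class SyntheticTruth:
    """Ground-truth roles assigned by :func:`generate_dataset`."""

    background_genes: list
    stable_genes: list
    cluster_membership: dict  # gene id -> cluster index
    true_edges: list  # planted direct couplings: (gene_x, gene_y, sign, group)
    chain_links: list  # direct x-z and z-y links realized by planted chains
    true_indirect_pairs: list  # (x, y, mediator z)
    de_genes_t0: dict  # gene id -> log2 effect size
    dynamic_genes: list  # every gene with a non-flat profile in some group

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def _smooth_shape(rng: np.random.Generator, n: int) -> np.ndarray:
    """Zero-mean, unit-variance smooth random profile over n timepoints."""
    raw = rng.standard_normal(n + 2)
    sm = np.convolve(raw, np.ones(3) / 3.0, mode="valid")
    sm = sm - sm.mean()
    sd = sm.std(ddof=0)
    if sd < 1e-12:  # pathological draw; fall back to a ramp
        sm = np.linspace(-1.0, 1.0, n)
        sd = sm.std(ddof=0)
    return sm / sd


def _peak_shape(timepoints: np.ndarray, peak: float, width: float = 2.5) -> np.ndarray:
    """Piecewise-linear rise/decay (in sampling order) peaking at ``peak``."""
    idx = np.arange(len(timepoints), dtype=float)
    i_peak = float(np.argmin(np.abs(timepoints - peak)))
    return np.clip(1.0 - np.abs(idx - i_peak) / width, 0.0, None)


def generate_dataset(config: SimulationConfig):
    """Simulate intensities for every array and return (dataset, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tp = np.asarray(config.timepoints_hours, dtype=float)
    T = len(tp)
    n = config.n_genes
    gene_ids = [_gene_id(i) for i in range(n)]

    # Noise-free log2 signal per (group, line, gene, timepoint).  Lines within
    # a group share the group signal except where a chain's biological link
    # noise (drawn per line) propagates downstream.
    baseline = np.zeros(n)
    baseline[list(config.background_idx)] = rng.normal(
        config.mu_background, config.sigma_background, config.n_background
    )
    hi_lo = config.mu_background + 5.0 * config.sigma_background
    n_expressed = n - config.n_background
    baseline[config.n_background:] = rng.uniform(hi_lo, hi_lo + 4.0, n_expressed)

    shapes = {g: np.zeros((n, T)) for g in GROUPS}  # zero-mean dynamic parts
    cluster_membership: dict[str, int] = {}
    for ci, (spec, idx) in enumerate(zip(config.cluster_specs, config.cluster_idx())):
        shape = spec.amplitude * _peak_shape(tp, spec.peak_time_h)
        for g in GROUPS:
            shapes[g][list(idx)] += shape
        for i in idx:
            cluster_membership[_gene_id(i)] = ci

    # roots of planted structures get independent smooth dynamic shapes
    amp = config.structure_amplitude
    edge_groups = {"both": list(GROUPS), "case": ["case"], "control": ["control"]}
    root_shape: dict[int, np.ndarray] = {}
    for e in config.planted_edges:
        root_shape[e.source] = amp * _smooth_shape(rng, T)
    for c in config.planted_chains:
        root_shape[c.x] = amp * _smooth_shape(rng, T)
    for i, s in root_shape.items():
        for g in GROUPS:
            shapes[g][i] = s

    true_edges = []
    de_genes: dict[str, float] = {}
    for ge in config.group_effects:
        if ge.kind == "constitutive_offset":  # applied below via offsets
            de_genes[_gene_id(ge.gene)] = ge.magnitude
        elif ge.kind == "profile_change":
            shapes[ge.group][ge.gene] = ge.magnitude * _smooth_shape(rng, T)
        elif ge.kind == "group_unique_dynamic":
            shapes[ge.group][ge.gene] = ge.magnitude * _smooth_shape(rng, T)
            other = "case" if ge.group == "control" else "control"
            shapes[other][ge.gene] = np.zeros(T)

    offsets = {g: np.zeros(n) for g in GROUPS}
    for ge in config.group_effects:
        if ge.kind == "constitutive_offset":
            offsets[ge.group][ge.gene] += ge.magnitude

    # Per-line noise-free-but-biological signal: chains inject per-line link
    # noise so the mediator's realised trajectory (not just its mean shape)
    # drives the downstream gene.
    lines = range(1, config.lines_per_group + 1)
    signal = {
        (g, d): baseline[:, None] + shapes[g] + offsets[g][:, None]
        for g in GROUPS
        for d in lines
    }
    for e in config.planted_edges:
        src = root_shape[e.source]
        for g in GROUPS:
            for d in lines:
                sig = signal[(g, d)]
                if g in edge_groups[e.group]:
                    link = rng.normal(0.0, config.link_noise_sd, T)
                    sig[e.target] = baseline[e.target] + e.sign * (src + link)
                else:
                    sig[e.target] = baseline[e.target]
        true_edges.append((_gene_id(e.source), _gene_id(e.target), e.sign, e.group))
    true_indirect, chain_links = [], []
    for c in config.planted_chains:
        src = root_shape[c.x]
        for g in GROUPS:
            for d in lines:
                sig = signal[(g, d)]
                z_traj = src + rng.normal(0.0, config.link_noise_sd, T)
                y_traj = z_traj + rng.normal(0.0, config.link_noise_sd, T)
                sig[c.z] = baseline[c.z] + z_traj
                sig[c.y] = baseline[c.y] + y_traj
        chain_links.append((_gene_id(c.x), _gene_id(c.z), 1, "both"))
        chain_links.append((_gene_id(c.z), _gene_id(c.y), 1, "both"))
        true_indirect.append((_gene_id(c.x), _gene_id(c.y), _gene_id(c.z)))

    # assemble arrays: measurement noise, then per-array affine distortion
    cols, meta_rows, data = [], [], []
    for g in GROUPS:
        for d in lines:
            sig = signal[(g, d)]
            for ti, t in enumerate(tp):
                aid = f"{'C' if g == 'control' else 'S'}{d}_t{t:g}"
                logv = sig[:, ti] + rng.normal(0.0, config.noise_sd, n)
                slope = 1.0 + rng.normal(0.0, config.array_scale_sd)
                intercept = rng.normal(0.0, config.array_offset_sd)
                logv = slope * logv + intercept
                cols.append(aid)
                data.append(np.exp2(logv))
                meta_rows.append(
                    {
                        "array_id": aid,
                        "group": g,
                        "line": f"{g}_line{d}",
                        "timepoint_h": float(t),
                        "duplicate_idx": d,
                    }
                )
    values = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    meta = pd.DataFrame(meta_rows).set_index("array_id")
    ds = ExpressionDataset(values, meta)

    dynamic = sorted(
        {
            _gene_id(i)
            for g in GROUPS
            for i in range(n)
            if np.ptp(shapes[g][i]) > 0
        }
        | {_gene_id(c.z) for c in config.planted_chains}
        | {_gene_id(c.y) for c in config.planted_chains}
        | {_gene_id(e.target) for e in config.planted_edges}
    )
    truth = SyntheticTruth(
        background_genes=[_gene_id(i) for i in config.background_idx],
        stable_genes=[_gene_id(i) for i in config.stable_idx],
        cluster_membership=cluster_membership,
        true_edges=true_edges,
        chain_links=chain_links,
        true_indirect_pairs=true_indirect,
        de_genes_t0=de_genes,
        dynamic_genes=dynamic,
    )
    return ds, truth


def generate_randomized_replicates(
    n_genes: int, n_reps: int, seed: int
) -> np.ndarray:
    """I.i.d. standard-normal genes x replicates matrix (null for calibration).

    No true associations exist in this data; it is the randomized input for
    Monte-Carlo calibration of the network thresholds.
    """
    if n_genes < 3 or n_reps < 3:
        raise ConfigError("n_genes and n_reps must both be >= 3")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_genes, n_reps))


def default_config(seed: int = 0) -> SimulationConfig:
    """The reference simulation: planted clusters, chains, group edges, DE genes."""
    cfg = SimulationConfig(seed=seed)
    f = cfg.free_idx.start
    cfg.planted_chains = [
        ChainSpec(f, f + 1, f + 2),
        ChainSpec(f + 3, f + 4, f + 5),
    ]
    cfg.planted_edges = [
        EdgeSpec(f + 6, f + 7, sign=1, group="both"),
        EdgeSpec(f + 8, f + 9, sign=-1, group="both"),
        EdgeSpec(f + 10, f + 11, sign=1, group="case"),
        EdgeSpec(f + 12, f + 13, sign=1, group="control"),
    ]
    cfg.group_effects = [
        GroupEffect(f + 14, "constitutive_offset", 2.0),
        GroupEffect(f + 15, "constitutive_offset", -2.0),
        GroupEffect(f + 16, "constitutive_offset", 2.5),
        GroupEffect(f + 17, "group_unique_dynamic", 2.0),
        GroupEffect(f + 18, "group_unique_dynamic", 2.0, group="control"),
    ]
    return cfg


def write_simulation(ds, truth, out_dir) -> dict:
    paths = write_dataset(ds, out_dir)
    truth_path = Path(out_dir) / "truth.json"
    truth.to_json(truth_path)
    paths["truth"] = truth_path
    return paths
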
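"""Synthetic purified references and in-silico bulk mixtures.

The reference generator emulates a purified-cell discovery panel: every
probe gets a baseline beta drawn uniformly from a configurable range; a
disjoint block of probes per Layer-1 group is shifted (half up, half down)
by ``delta_beta_group`` in that group's samples, a disjoint block per leaf
cell type is shifted by ``delta_beta_leaf`` in that leaf's samples, and
i.i.d. Gaussian noise of sd ``noise_sd`` is added before clipping to
[0, 1]. Baselines on signal probes are drawn so the shifted value stays
inside [0, 1] with headroom for the noise, keeping the planted effect
sizes intact.

Bulk mixtures follow the published validation recipe: per mixture, draw k
Uniform(0, 1) numbers and normalize them into proportions; draw purified
samples per cell type without replacement and average them into a mean
matrix M; the mixture column is M @ pi, optionally plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .hierarchy import LAYER1, CellHierarchy, DEFAULT_HIERARCHY
from .io import BetaMatrix
from .library import ReferenceLibrary

__all__ = [
    "SyntheticReferenceConfig",
    "MixtureTruth",
    "make_synthetic_reference",
    "sample_mixture_proportions",
    "build_mixture_matrix",
    "exact_mixture_from_library",
]


@dataclass(frozen=True)
class SyntheticReferenceConfig:
    """Conditions for the synthetic purified panel.

    Defaults are the desk-scale stand-in for a purified brain discovery
    panel: 2,000 probes, 5 samples per cell type, strong group-level
    markers (delta 0.5), slightly weaker leaf-level markers (delta 0.4), 20
    marker probes per class and a within-cell-type noise sd of 0.02 beta
    units.
    """

    n_probes: int = 2000
    n_samples_per_type: int = 5
    delta_beta_group: float = 0.5
    delta_beta_leaf: float = 0.4
    n_signal_probes_per_class: int = 20
    noise_sd: float = 0.02
    baseline_beta_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.baseline_beta_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValidationError("baseline_beta_range must satisfy 0 <= lo < hi <= 1")
        for name in ("delta_beta_group", "delta_beta_leaf", "noise_sd"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class MixtureTruth:
    """Designed per-mixture cell-type proportions (rows on the unit simplex)."""

    proportions: pd.DataFrame  # mixtures x cell types
    seed: int

    def __post_init__(self) -> None:
        p = self.proportions.to_numpy()
        if (p < 0).any() or np.abs(p.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValidationError("truth rows must be nonnegative and sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.proportions.columns)


def _signal_baseline(
    rng: np.random.Generator, n: int, lo: float, hi: float, delta: float, sign: int, margin: float
) -> np.ndarray:
    """Baselines for signal probes such that baseline + sign*delta stays in [0,1]."""
    if sign > 0:
        a, b = lo, min(hi, 1.0 - delta - margin)
    else:
        a, b = max(lo, delta + margin), hi
    if b <= a:
        raise ValidationError(
            f"baseline range ({lo}, {hi}) leaves no room for a shift of "
            f"{sign * delta:+g} with margin {margin:g}"
        )
    return rng.uniform(a, b, size=n)


def make_synthetic_reference(
    cfg: SyntheticReferenceConfig, hierarchy: CellHierarchy = DEFAULT_HIERARCHY
) -> tuple[BetaMatrix, pd.DataFrame, dict[str, list[str]]]:
    """Generate a purified reference panel with planted hierarchical signal.

    Returns (beta matrix, sample annotation, planted-probe map). The probe
    map keys are the Layer-1 node and every class label, each mapped to its
    disjoint planted marker block (within a block, probes alternate
    hyper/hypo direction). Identical seed -> bit-identical output.
    """
    leaves = list(hierarchy.leaves)
    groups = list(hierarchy.group_labels)
    classes = groups + leaves
    n_signal = cfg.n_signal_probes_per_class * len(classes)
    if n_signal > cfg.n_probes:
        raise ValidationError(
            f"{n_signal} signal probes exceed n_probes={cfg.n_probes}"
        )
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.baseline_beta_range
    margin = min(0.05 + 4.0 * cfg.noise_sd, 0.2)

    probe_ids = [f"cg{i:07d}" for i in range(cfg.n_probes)]
    sample_ids: list[str] = []
    sample_leaf: list[str] = []
    for leaf in leaves:
        for r in range(cfg.n_samples_per_type):
            sample_ids.append(f"{leaf}_{r + 1}")
            sample_leaf.append(leaf)
    n_samples = len(sample_ids)
    leaf_arr = np.asarray(sample_leaf)
    group_arr = np.asarray([hierarchy.group_of(l) for l in sample_leaf])

    baseline = rng.uniform(lo, hi, size=cfg.n_probes)
    values = np.tile(baseline[:, None], (1, n_samples))

    planted: dict[str, list[str]] = {}
    cursor = 0
    for cls in classes:
        block = np.arange(cursor, cursor + cfg.n_signal_probes_per_class)
        cursor += cfg.n_signal_probes_per_class
        planted[cls] = [probe_ids[i] for i in block]
        delta = cfg.delta_beta_group if cls in groups else cfg.delta_beta_leaf
        affected = (group_arr == cls) if cls in groups else (leaf_arr == cls)
        signs = np.where(np.arange(block.size) % 2 == 0, 1, -1)
        for sign in (1, -1):
            rows = block[signs == sign]
            if rows.size == 0:
                continue
            base = _signal_baseline(rng, rows.size, lo, hi, delta, sign, margin)
            values[rows, :] = base[:, None]
            values[np.ix_(rows, np.where(affected)[0])] = (base + sign * delta)[:, None]
    planted[LAYER1] = [p for g in groups for p in planted[g]]

    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 1.0)

    beta = BetaMatrix(probe_ids, sample_ids, values)
    ann = pd.DataFrame({"sample_id": sample_ids, "cell_type": sample_leaf})
    return beta, ann, planted


def sample_mixture_proportions(
    n_mixtures: int, cell_types: list[str], seed: int
) -> MixtureTruth:
    """Uniform-then-normalize proportions: k Uniform(0,1) draws per mixture,
    divided by their sum. Rows land exactly on the unit simplex."""
    if n_mixtures < 1:
        raise ValidationError("n_mixtures must be >= 1")
    if not cell_types:
        raise ValidationError("cell_types must be nonempty")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=(n_mixtures, len(cell_types)))
    p = u / u.sum(axis=1, keepdims=True)
    props = pd.DataFrame(
        p,
        index=[f"mix_{i + 1}" for i in range(n_mixtures)],
        columns=list(cell_types),
    )
    return MixtureTruth(proportions=props, seed=seed)


def build_mixture_matrix(
    purified: BetaMatrix,
    ann: pd.DataFrame,
    truth: MixtureTruth,
    samples_per_type_draw: int | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[BetaMatrix, dict]:
    """Assemble in-silico bulk mixtures from purified profiles.

    Per mixture and cell type, ``samples_per_type_draw`` purified samples
    are drawn without replacement (default: all available) and averaged
    into a per-type mean matrix M; the mixture column is M @ pi, plus
    optional N(0, noise_sd) noise, clipped to [0, 1]. The returned
    metadata carries the per-probe, per-type standard deviations across
    the drawn samples (averaged over mixtures) and the draw record.
    """
    labels = ann.set_index("sample_id")["cell_type"]
    by_type: dict[str, list[str]] = {}
    for ct in truth.cell_types:
        ids = list(labels.index[labels == ct])
        if not ids:
            raise ValidationError(f"cell type {ct!r} absent from the purified panel")
        by_type[ct] = ids
    n_avail = {ct: len(ids) for ct, ids in by_type.items()}
    draw = samples_per_type_draw
    if draw is None:
        draw = min(n_avail.values())
    if draw < 1 or any(draw > n for n in n_avail.values()):
        raise ValidationError(
            f"samples_per_type_draw={draw} exceeds available purified samples "
            f"(min {min(n_avail.values())})"
        )
    rng = np.random.default_rng(seed)
    frame = purified.to_dataframe()
    n_probes = len(purified.probe_ids)
    k = len(truth.cell_types)
    mix = np.empty((n_probes, len(truth.sample_ids)))
    sd_accum = np.zeros((n_probes, k))
    draws: dict[str, dict[str, list[str]]] = {}
    for j, mix_id in enumerate(truth.sample_ids):
        M = np.empty((n_probes, k))
        draws[mix_id] = {}
        for ci, ct in enumerate(truth.cell_types):
            chosen = list(rng.choice(by_type[ct], size=draw, replace=False))
            draws[mix_id][ct] = chosen
            block = frame[chosen].to_numpy(dtype=float)
            M[:, ci] = block.mean(axis=1)
            sd_accum[:, ci] += block.std(axis=1, ddof=1) if draw > 1 else 0.0
        mix[:, j] = M @ truth.proportions.loc[mix_id].to_numpy()
    if noise_sd > 0:
        mix = mix + rng.normal(0.0, noise_sd, size=mix.shape)
    mix = np.clip(mix, 0.0, 1.0)
    beta = BetaMatrix(list(purified.probe_ids), list(truth.sample_ids), mix)
    per_type_sd = pd.DataFrame(
        sd_accum / len(truth.sample_ids),
        index=purified.probe_ids,
        columns=truth.cell_types,
    )
    meta = {
        "samples_per_type_draw": draw,
        "noise_sd": noise_sd,
        "seed": seed,
        "per_type_sd": per_type_sd,
        "draws": draws,
    }
    return beta, meta


def exact_mixture_from_library(
    library: ReferenceLibrary, leaf_proportions: pd.DataFrame
) -> BetaMatrix:
    """Bulk profiles that are exact combinations of the library's mean columns.

    Every Layer-1 library probe carries X_layer1 @ (group totals) and every
    Layer-2 node probe carries X_node @ (absolute leaf proportions of that
    group) plus, when the node has a complement profile, complement *
    (1 - group total) for the off-group mass, so each node's constrained
    projection sees a zero-residual problem and hierarchical recovery is
    exact up to solver precision. Requires disjoint sub-library probe sets
    (e.g. sub-libraries built on the generator's planted blocks).
    """
    hierarchy = library.hierarchy
    leaves = list(hierarchy.leaves)
    missing = [l for l in leaves if l not in leaf_proportions.columns]
    if missing:
        raise ValidationError(f"leaf proportions lack cell types: {missing}")
    pi = leaf_proportions[leaves].to_numpy(dtype=float)
    if (pi < 0).any():
        raise ValidationError("leaf proportions must be nonnegative")
    seen: set[str] = set()
    rows: list[pd.DataFrame] = []
    node_of_group = library.hierarchy.layer2_nodes()

    l1 = library.sub_libraries[LAYER1]
    group_totals = np.stack(
        [
            leaf_proportions[list(hierarchy.groups[g])].sum(axis=1).to_numpy()
            for g in hierarchy.group_labels
        ],
        axis=1,
    )
    rows.append(
        pd.DataFrame(
            l1.means @ group_totals.T, index=l1.probe_ids, columns=leaf_proportions.index
        )
    )
    seen.update(l1.probe_ids)
    for node, group in node_of_group.items():
        sub = library.sub_libraries[node]
        overlap = seen & set(sub.probe_ids)
        if overlap:
            raise ValidationError(
                f"sub-library probe sets overlap ({node}: {sorted(overlap)[:3]}...); "
                "exact per-node mixtures need disjoint probe sets"
            )
        coeff = leaf_proportions[list(hierarchy.groups[group])].to_numpy()
        vals = sub.means @ coeff.T
        if sub.complement_mean is not None:
            off_mass = 1.0 - coeff.sum(axis=1)
            vals = vals + np.outer(sub.complement_mean, off_mass)
        rows.append(
            pd.DataFrame(vals, index=sub.probe_ids, columns=leaf_proportions.index)
        )
        seen.update(sub.probe_ids)
    stacked = pd.concat(rows, axis=0)
    return BetaMatrix.from_dataframe(stacked)
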
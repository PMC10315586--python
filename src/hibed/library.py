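"""Hierarchical reference-library construction.

Cell-type-specific CpGs are found per hierarchy node by one-vs-rest
differential methylation with empirical-Bayes (limma-style) variance
moderation, ranked by moderated t-statistic, and pooled into one
sub-library per node (Layer 1 over the three cell groups; Layer 2A/2B/2C
over each group's leaf types). Candidate probe sets can be scored with the
dispersion separability criterion (DSC), the ratio of between-class to
within-class dispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from ._errors import ComputeError, ValidationError
from .hierarchy import LAYER1, CellHierarchy, DEFAULT_HIERARCHY
from .io import BetaMatrix

__all__ = [
    "ModeratedTestResult",
    "SubLibrary",
    "ReferenceLibrary",
    "DSCValue",
    "moderated_one_vs_rest",
    "select_top_cpgs",
    "build_sub_library",
    "build_hibed_library",
    "compute_dsc",
]


@dataclass
class ModeratedTestResult:
    """One-vs-rest moderated test statistics, per probe and target class.

    ``effects[p, c]`` is mean beta of class c minus mean beta of the rest
    (so positive = hypermethylated in the class); ``t`` is the moderated
    t-statistic after squeezing per-probe residual variances toward the
    fitted prior.
    """

    probe_ids: list[str]
    classes: list[str]
    effects: np.ndarray  # probes x classes
    t: np.ndarray  # probes x classes
    n_target: dict[str, int]
    n_rest: dict[str, int]

    def effect_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.effects, index=self.probe_ids, columns=self.classes)

    def t_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.t, index=self.probe_ids, columns=self.classes)

    def direction(self) -> pd.DataFrame:
        """'hyper' where effect > 0, 'hypo' where effect < 0."""
        return self.effect_frame().map(lambda e: "hyper" if e > 0 else "hypo")


@dataclass
class SubLibrary:
    """Marker probe set and per-cell-type mean profile for one hierarchy node.

    ``complement_mean`` (Layer-2 nodes) is the mean profile of all reference
    samples OUTSIDE the node's cell types over the same probes. It enters
    the node's constrained projection as a nuisance column so that
    off-group cell mass in the bulk is modelled instead of biasing the
    within-group proportions.
    """

    node_label: str
    cell_types: list[str]
    probe_ids: list[str]
    means: np.ndarray  # probes x cell types
    complement_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.complement_mean is not None:
            self.complement_mean = np.asarray(self.complement_mean, dtype=float).ravel()
            if self.complement_mean.shape != (len(self.probe_ids),):
                raise ValidationError(
                    f"{self.node_label}: complement profile length "
                    f"{self.complement_mean.size} != {len(self.probe_ids)} probes"
                )
            if np.nanmin(self.complement_mean) < 0 or np.nanmax(self.complement_mean) > 1:
                raise ValidationError(f"{self.node_label}: complement outside [0, 1]")
        if self.means.shape != (len(self.probe_ids), len(self.cell_types)):
            raise ValidationError(
                f"{self.node_label}: means shape {self.means.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.cell_types)} cell types"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError(f"{self.node_label}: duplicate probes")
        if len(self.probe_ids) < len(self.cell_types):
            raise ValidationError(
                f"{self.node_label}: {len(self.probe_ids)} probes < "
                f"{len(self.cell_types)} cell types (unidentifiable)"
            )
        if np.nanmin(self.means) < 0 or np.nanmax(self.means) > 1:
            raise ValidationError(f"{self.node_label}: means outside [0, 1]")

    def means_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=self.probe_ids, columns=self.cell_types)


@dataclass
class ReferenceLibrary:
    """Four-sub-library hierarchical reference (Layer 1 plus one per group)."""

    hierarchy: CellHierarchy
    sub_libraries: dict[str, SubLibrary]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nodes = self.hierarchy.layer2_nodes()
        expected = [LAYER1, *nodes]
        missing = [n for n in expected if n not in self.sub_libraries]
        if missing:
            raise ValidationError(f"library is missing sub-libraries: {missing}")
        l1 = self.sub_libraries[LAYER1]
        if list(l1.cell_types) != list(self.hierarchy.group_labels):
            raise ValidationError(
                "Layer1 cell types must equal the hierarchy group labels"
            )
        for node, group in nodes.items():
            sub = self.sub_libraries[node]
            if list(sub.cell_types) != list(self.hierarchy.groups[group]):
                raise ValidationError(
                    f"{node} cell types must equal the leaves of group {group!r}"
                )

    @property
    def node_labels(self) -> list[str]:
        return list(self.sub_libraries)


@dataclass(frozen=True)
class DSCValue:
    """Dispersion separability: between-class over within-class dispersion."""

    value: float
    between_dispersion: float
    within_dispersion: float


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def squeeze_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float, float]:
    """Shrink per-probe residual variances toward a fitted inverse-chi-square prior.

    Fits prior degrees of freedom d0 and prior variance s0^2 by moment
    matching on log variances, then returns the posterior variances
    (d0*s0^2 + df*s2) / (d0 + df) together with (d0, s0^2). Probes with
    zero sample variance contribute nothing to the fit but are still
    squeezed. If every variance is zero the data are degenerate and the
    variances are returned unchanged with d0 = 0.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if df <= 0 or pos.sum() < 2:
        return s2.copy(), 0.0, 0.0
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    n = e.size
    evar = float(np.mean((e - emean) ** 2) * n / (n - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array(evar)))
        s0_2 = float(
            math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
        )
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        d0 = math.inf
        s0_2 = float(math.exp(emean))
        post = np.full_like(s2, s0_2)
    return post, d0, s0_2


def moderated_one_vs_rest(
    beta: BetaMatrix, ann: pd.DataFrame, classes: list[str] | None = None
) -> ModeratedTestResult:
    """One-vs-rest moderated t-statistics for every probe and class.

    For each class c, the effect is mean(beta | c) - mean(beta | not c) and
    the t-statistic uses the pooled two-group residual variance squeezed by
    :func:`squeeze_variances`. Every class needs >= 2 samples; the beta
    matrix must be complete over its probes.
    """
    labels = ann.set_index("sample_id")["cell_type"].reindex(beta.sample_ids)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])[:5]
        raise ValidationError(f"samples without annotation: {missing!r}")
    if classes is None:
        classes = list(dict.fromkeys(labels))
    if len(beta.probe_ids) == 0:
        raise ValidationError("beta matrix has zero probes")
    if np.isnan(beta.values).any():
        raise ValidationError("beta matrix has missing values; drop them first")

    values = beta.values
    n_total = values.shape[1]
    effects = np.zeros((values.shape[0], len(classes)))
    tstats = np.zeros_like(effects)
    n_target: dict[str, int] = {}
    n_rest: dict[str, int] = {}
    for ci, cls in enumerate(classes):
        mask = (labels == cls).to_numpy()
        n1 = int(mask.sum())
        n2 = n_total - n1
        if n1 < 2 or n2 < 2:
            raise ValidationError(
                f"class {cls!r} needs >=2 samples in target and rest "
                f"(got {n1} vs {n2})"
            )
        n_target[cls], n_rest[cls] = n1, n2
        x1 = values[:, mask]
        x2 = values[:, ~mask]
        m1 = x1.mean(axis=1)
        m2 = x2.mean(axis=1)
        effect = m1 - m2
        ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
        df = n1 + n2 - 2
        s2 = ss / df
        s2_post, _, _ = squeeze_variances(s2, df)
        denom = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / denom
        t[np.isnan(t)] = 0.0  # 0/0: flat probe, no evidence
        effects[:, ci] = effect
        tstats[:, ci] = t
    return ModeratedTestResult(
        probe_ids=list(beta.probe_ids),
        classes=list(classes),
        effects=effects,
        t=tstats,
        n_target=n_target,
        n_rest=n_rest,
    )


# ---------------------------------------------------------------------------
# probe selection


def _rank_probes(probe_ids: list[str], t: np.ndarray, largest: bool) -> list[str]:
    # stable deterministic order: by t (desc for hyper / asc for hypo),
    # probe-ID lexicographic tiebreak
    key_t = -t if largest else t
    ids = np.asarray(probe_ids)
    order = np.lexsort((ids, key_t))
    return list(ids[order])


def select_top_cpgs(
    res: ModeratedTestResult, n_per_type: int, mode: str = "hybrid"
) -> tuple[dict[str, dict[str, list[str]]], list[str]]:
    """Pick the top-ranked marker probes per class and pool them.

    mode='hyper' takes the n_per_type largest moderated t per class,
    'hypo' the most negative, and 'hybrid' the union of both. Returns
    (per-class picks keyed by direction, pooled unique probe list sorted
    by probe ID). Deterministic: ties break lexicographically on probe ID.
    """
    if mode not in ("hyper", "hypo", "hybrid"):
        raise ValidationError(f"unknown selection mode {mode!r}")
    if n_per_type < 1:
        raise ValidationError("n_per_type must be >= 1")
    if n_per_type > len(res.probe_ids):
        raise ValidationError(
            f"n_per_type={n_per_type} exceeds {len(res.probe_ids)} available probes"
        )
    per_class: dict[str, dict[str, list[str]]] = {}
    pooled: set[str] = set()
    for ci, cls in enumerate(res.classes):
        picks: dict[str, list[str]] = {}
        if mode in ("hyper", "hybrid"):
            picks["hyper"] = _rank_probes(res.probe_ids, res.t[:, ci], largest=True)[
                :n_per_type
            ]
        if mode in ("hypo", "hybrid"):
            picks["hypo"] = _rank_probes(res.probe_ids, res.t[:, ci], largest=False)[
                :n_per_type
            ]
        per_class[cls] = picks
        for lst in picks.values():
            pooled.update(lst)
    return per_class, sorted(pooled)


def build_sub_library(
    beta: BetaMatrix,
    labels: pd.Series,
    classes: list[str],
    probes: list[str],
    node_label: str,
    complement_samples: list[str] | None = None,
) -> SubLibrary:
    """Average purified profiles per class over the chosen probes.

    ``labels`` maps sample ID to the node's class label (group label at
    Layer 1 — leaf samples pooled into their group — leaf label at Layer 2).
    ``complement_samples`` (reference samples outside the node's classes)
    are averaged into the node's complement profile when given.
    """
    sub_beta = beta.select_probes(probes)
    labels = labels.reindex(sub_beta.sample_ids)
    means = np.empty((len(probes), len(classes)))
    for ci, cls in enumerate(classes):
        mask = (labels == cls).to_numpy()
        if mask.sum() == 0:
            raise ValidationError(f"{node_label}: class {cls!r} has zero samples")
        means[:, ci] = np.nanmean(sub_beta.values[:, mask], axis=1)
    complement = None
    if complement_samples:
        comp_beta = beta.select_probes(probes).select_samples(complement_samples)
        complement = np.nanmean(comp_beta.values, axis=1)
    return SubLibrary(
        node_label=node_label,
        cell_types=list(classes),
        probe_ids=list(probes),
        means=means,
        complement_mean=complement,
    )


def build_hibed_library(
    beta: BetaMatrix,
    ann: pd.DataFrame,
    hierarchy: CellHierarchy = DEFAULT_HIERARCHY,
    n_per_type: int = 50,
    mode: str = "hybrid",
) -> ReferenceLibrary:
    """Build the full hierarchical reference from purified-sample betas.

    Runs one-vs-rest moderated selection once at Layer 1 (classes = cell
    groups, all samples) and once per multi-leaf group (classes = that
    group's leaves, only its samples), then assembles per-node mean
    profiles. Probes with any missing value in the reference cohort are
    dropped before selection. The published default is 50 CpGs per
    direction per cell type, hybrid (hyper + hypo) selection.
    """
    complete = ~np.isnan(beta.values).any(axis=1)
    if not complete.all():
        beta = beta.select_probes([p for p, ok in zip(beta.probe_ids, complete) if ok])
    leaf_labels = ann.set_index("sample_id")["cell_type"].reindex(beta.sample_ids)
    if leaf_labels.isna().any():
        raise ValidationError("every sample in the beta matrix needs an annotation")
    unknown = set(leaf_labels) - set(hierarchy.leaves)
    if unknown:
        raise ValidationError(f"annotation labels not in hierarchy: {sorted(unknown)}")
    for leaf in hierarchy.leaves:
        if (leaf_labels == leaf).sum() < 2:
            raise ValidationError(f"cell type {leaf!r} needs >=2 reference samples")

    group_labels = leaf_labels.map(hierarchy.group_of)
    subs: dict[str, SubLibrary] = {}

    # Layer 1: discriminate the groups using all samples
    ann_l1 = pd.DataFrame(
        {"sample_id": group_labels.index, "cell_type": group_labels.values}
    )
    res = moderated_one_vs_rest(beta, ann_l1, classes=list(hierarchy.group_labels))
    _, pooled = select_top_cpgs(res, n_per_type, mode)
    subs[LAYER1] = build_sub_library(
        beta, group_labels, list(hierarchy.group_labels), pooled, LAYER1
    )

    # Layer 2: one node per multi-leaf group, restricted to its samples
    for node, group in hierarchy.layer2_nodes().items():
        leaves = list(hierarchy.groups[group])
        samples = list(leaf_labels.index[group_labels == group])
        sub_beta = beta.select_samples(samples)
        ann_node = pd.DataFrame(
            {"sample_id": samples, "cell_type": leaf_labels.loc[samples].values}
        )
        off_samples = [s for s in beta.sample_ids if s not in set(samples)]
        try:
            res = moderated_one_vs_rest(sub_beta, ann_node, classes=leaves)
            _, pooled = select_top_cpgs(res, n_per_type, mode)
            subs[node] = build_sub_library(
                beta, leaf_labels, leaves, pooled, node,
                complement_samples=off_samples,
            )
        except ValidationError as exc:
            raise ValidationError(f"{node} ({group}): {exc}") from exc

    return ReferenceLibrary(
        hierarchy=hierarchy,
        sub_libraries=subs,
        provenance={
            "n_per_type": int(n_per_type),
            "direction_mode": mode,
            "n_reference_samples": len(beta.sample_ids),
            "n_reference_probes": len(beta.probe_ids),
        },
    )


# ---------------------------------------------------------------------------
# dispersion separability criterion


def compute_dsc(beta: BetaMatrix, ann: pd.DataFrame, probes: list[str]) -> DSCValue:
    """Between-class over within-class dispersion on a probe subset.

    between = sqrt((1/N) sum_k n_k ||c_k - c||^2), within =
    sqrt((1/N) sum_k sum_{i in k} ||x_i - c_k||^2) with class centroids c_k
    and global centroid c. Higher = better class separation. Duplicated
    within-class samples with distinct centroids give an infinite value;
    fully degenerate data raise.
    """
    labels = ann.set_index("sample_id")["cell_type"].reindex(beta.sample_ids)
    if labels.isna().any():
        raise ValidationError("samples without annotation")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValidationError("DSC needs >=2 classes")
    x = beta.select_probes(probes).values.T  # samples x probes
    n_total = x.shape[0]
    global_centroid = x.mean(axis=0)
    between_sq = 0.0
    within_sq = 0.0
    for cls in classes:
        mask = (labels == cls).to_numpy()
        xk = x[mask]
        ck = xk.mean(axis=0)
        between_sq += mask.sum() * float(np.sum((ck - global_centroid) ** 2))
        within_sq += float(np.sum((xk - ck) ** 2))
    between = math.sqrt(between_sq / n_total)
    within = math.sqrt(within_sq / n_total)
    if between == 0.0 and within == 0.0:
        raise ComputeError("degenerate: all samples identical over the probe set")
    value = math.inf if within == 0.0 else between / within
    return DSCValue(value=value, between_dispersion=between, within_dispersion=within)
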
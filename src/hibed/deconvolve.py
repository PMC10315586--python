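"""Constrained-projection estimation of cell-type proportions.

A bulk methylation profile y is modelled as y = X pi + e, where the
columns of X are the reference mean profiles of the node's cell types and
pi is the proportion vector, constrained to pi >= 0 with sum(pi) <= 1
(Layer 1; the remainder is reported as "unknown") or sum(pi) = 1. The
quadratic program is solved exactly: the inequality-constrained problem is
nonnegative least squares unless the sum constraint is active, in which
case the equality-constrained optimum is found by enumerating active sets
of the KKT system — exact to machine precision and fully deterministic.

Layer-2 deconvolution follows the three-step hierarchical scheme: estimate
group proportions with the Layer-1 library, estimate within-group
(conditional) proportions with each group's Layer-2 library, renormalize
the conditionals to sum to one, and weight them by the group proportion.

The model-object surface mirrors statsmodels: build ``HiBED(bulk,
library)``, call ``.fit(layer=2)``, inspect the returned
:class:`HiBEDResults`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from . import __version__ as _version
from ._errors import ComputeError, CoverageError, ValidationError
from .hierarchy import LAYER1, CellHierarchy
from .io import BetaMatrix
from .library import ReferenceLibrary, SubLibrary

UNKNOWN = "unknown"

# coverage thresholds on the fraction of library probes present in the bulk
COVERAGE_ERROR = 0.5
COVERAGE_WARN = 0.8

_SOLVER_META = {
    "solver": "active-set KKT enumeration + NNLS",
    "objective_tolerance": 1e-9,
    "negativity_clip": 1e-10,
}


class CoverageWarning(UserWarning):
    """Fewer than 80% of a sub-library's probes were found in the bulk."""


# ---------------------------------------------------------------------------
# the quadratic program


def _solve_support(
    G: np.ndarray, b: np.ndarray, support: tuple[int, ...], total: float
) -> np.ndarray | None:
    """Equality-constrained LS on one support: min pi' G pi - 2 b' pi, sum = total."""
    k = len(support)
    idx = list(support)
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = G[np.ix_(idx, idx)]
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.append(b[idx], total)
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        if abs(sol[:k].sum() - total) > 1e-8:
            return None
    pi_s = sol[:k]
    if (pi_s < -1e-9).any():
        return None
    return np.clip(pi_s, 0.0, None)


def _qp_eq(X: np.ndarray, y: np.ndarray, total: float = 1.0) -> np.ndarray:
    """argmin ||y - X pi||^2 s.t. pi >= 0, sum(pi) = total, by support enumeration.

    Exact for any column count small enough to enumerate (the optimum's
    positive support solves its own equality-constrained LS, so scanning
    all supports and keeping the feasible minimum finds it).
    """
    k = X.shape[1]
    if k > 16:
        raise ComputeError(f"{k} cell types exceed the exact solver's limit (16)")
    if total <= 0.0:
        return np.zeros(k)
    G = X.T @ X
    b = X.T @ y
    best_obj = np.inf
    best = None
    for size in range(1, k + 1):
        for support in itertools.combinations(range(k), size):
            pi_s = _solve_support(G, b, support, total)
            if pi_s is None:
                continue
            pi = np.zeros(k)
            pi[list(support)] = pi_s
            obj = float(pi @ G @ pi - 2.0 * b @ pi)
            if obj < best_obj - 1e-12:
                best_obj = obj
                best = pi
    if best is None:  # cannot happen: singleton supports are always feasible
        raise ComputeError("no feasible support found")
    return best


def cp_qp(
    y: np.ndarray, X: np.ndarray, sum_mode: str = "le_one", sum_target: float = 1.0
) -> np.ndarray:
    """Constrained projection of a bulk profile onto reference mean profiles.

    Solves argmin ||y - X pi||^2 subject to pi >= 0 and either
    sum(pi) <= sum_target (``le_one``) or sum(pi) = sum_target
    (``eq_one``); the target defaults to 1. Exact and deterministic;
    duplicate identical columns only trigger a warning (ties resolved by
    the solver's fixed enumeration order).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("X must be a matrix with >=2 cell-type columns")
    if X.shape[0] != y.size:
        raise ValidationError(
            f"dimension mismatch: y has {y.size} probes, X has {X.shape[0]}"
        )
    if X.shape[0] < X.shape[1]:
        raise ValidationError("need at least as many probes as cell types")
    if sum_mode not in ("le_one", "eq_one"):
        raise ValidationError(f"unknown sum_mode {sum_mode!r}")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValidationError("missing values must be removed before solving")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(
            "reference matrix is rank deficient; proportions are not unique",
            UserWarning,
            stacklevel=2,
        )
    if sum_target < 0.0:
        raise ValidationError("sum_target must be nonnegative")
    if sum_mode == "le_one":
        pi, _ = nnls(X, y)
        if pi.sum() <= sum_target + 1e-10:
            # sum constraint inactive: the NNLS optimum is the QP optimum
            pi = np.clip(pi, 0.0, None)
            return pi
    pi = _qp_eq(X, y, total=sum_target)
    return np.clip(pi, 0.0, None)


# ---------------------------------------------------------------------------
# node-local deconvolution


@dataclass
class ProportionEstimate:
    """Samples x cell-types proportion matrix with layer metadata."""

    values: pd.DataFrame  # samples as rows, cell types as columns
    layer: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        from .io import write_proportions

        write_proportions(self.values, path)


def deconvolve_node(
    bulk: BetaMatrix, sub: SubLibrary, sum_mode: str = "le_one"
) -> ProportionEstimate:
    """Fit one sub-library's QP to every bulk sample.

    Restricts to the probes shared between bulk and library; probes missing
    for an individual sample are dropped from that sample's fit only. Warns
    below 80% library coverage, errors below 50%. When the sub-library
    carries a complement profile it is appended as a nuisance column
    (absorbing off-group cell mass) and its coefficient is reported in the
    metadata, not among the cell-type proportions.
    """
    present = [p for p in sub.probe_ids if p in set(bulk.probe_ids)]
    n_lib = len(sub.probe_ids)
    frac = len(present) / n_lib if n_lib else 0.0
    if frac < COVERAGE_ERROR:
        raise CoverageError(
            f"insufficient library coverage at {sub.node_label}: "
            f"{len(present)}/{n_lib} probes present"
        )
    if frac < COVERAGE_WARN:
        warnings.warn(
            f"{sub.node_label}: only {len(present)}/{n_lib} library probes "
            "present in bulk",
            CoverageWarning,
            stacklevel=2,
        )
    sub_frame = sub.means_frame().loc[present]
    bulk_frame = bulk.to_dataframe().loc[present]
    X_full = sub_frame.to_numpy()
    k = len(sub.cell_types)
    if sub.complement_mean is not None:
        comp = pd.Series(sub.complement_mean, index=sub.probe_ids).loc[present]
        X_full = np.column_stack([X_full, comp.to_numpy()])
    out = np.empty((len(bulk.sample_ids), X_full.shape[1]))
    used = np.empty(len(bulk.sample_ids), dtype=int)
    for j, sample in enumerate(bulk.sample_ids):
        y = bulk_frame[sample].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() / n_lib < COVERAGE_ERROR:
            raise CoverageError(
                f"insufficient library coverage at {sub.node_label} for sample "
                f"{sample!r}: {int(ok.sum())}/{n_lib} usable probes"
            )
        out[j] = cp_qp(y[ok], X_full[ok], sum_mode=sum_mode)
        used[j] = int(ok.sum())
    values = pd.DataFrame(out[:, :k], index=bulk.sample_ids, columns=sub.cell_types)
    metadata = {
        "node": sub.node_label,
        "sum_mode": sum_mode,
        "library_probes": n_lib,
        "probes_used": dict(zip(bulk.sample_ids, used.tolist())),
        **_SOLVER_META,
    }
    if sub.complement_mean is not None:
        metadata["complement_proportion"] = dict(
            zip(bulk.sample_ids, out[:, k].tolist())
        )
    return ProportionEstimate(values=values, metadata=metadata)


# ---------------------------------------------------------------------------
# hierarchical model


class HiBED:
    """Hierarchical deconvolution model for one bulk beta matrix.

    Parameters
    ----------
    bulk : BetaMatrix
        Probes x samples bulk methylation matrix.
    library : ReferenceLibrary
        Hierarchical reference built by
        :func:`hibed.library.build_hibed_library` or loaded from disk.
    """

    def __init__(self, bulk: BetaMatrix, library: ReferenceLibrary):
        self.bulk = bulk
        self.library = library

    @classmethod
    def from_files(cls, bulk_path, library_path, transpose: bool = False) -> "HiBED":
        from .io import load_library, read_beta_matrix

        return cls(read_beta_matrix(bulk_path, transpose=transpose), load_library(library_path))

    def fit(self, layer: int = 2, sum_mode: str = "le_one") -> "HiBEDResults":
        """Estimate proportions at the requested layer of the hierarchy."""
        if layer not in (1, 2):
            raise ValidationError("layer must be 1 or 2")
        hierarchy = self.library.hierarchy
        l1 = deconvolve_node(self.bulk, self.library.sub_libraries[LAYER1], sum_mode)
        layer1 = l1.values.clip(lower=0.0)
        layer1[UNKNOWN] = (1.0 - layer1.sum(axis=1)).clip(lower=0.0)
        nodes_meta = {LAYER1: l1.metadata}
        if layer == 1:
            return HiBEDResults(
                model=self,
                layer=1,
                proportions=layer1,
                layer1=layer1,
                conditional={},
                metadata=nodes_meta,
            )

        node_of_group = hierarchy.layer2_nodes()
        conditional: dict[str, pd.DataFrame] = {}
        leaf_cols: dict[str, pd.Series] = {}
        for group in hierarchy.group_labels:
            leaves = list(hierarchy.groups[group])
            if len(leaves) == 1:
                # single-leaf group: the group proportion passes through
                leaf_cols[leaves[0]] = layer1[group]
                continue
            node = next(n for n, g in node_of_group.items() if g == group)
            est = deconvolve_node(self.bulk, self.library.sub_libraries[node], sum_mode)
            cond = est.values.clip(lower=0.0)
            sums = cond.sum(axis=1)
            degenerate = sums <= 0.0
            if degenerate.any():
                cond.loc[degenerate, :] = 1.0 / len(leaves)
                sums = cond.sum(axis=1)
                if (layer1.loc[degenerate[degenerate].index, group] > 1e-12).any():
                    warnings.warn(
                        f"{node}: all-zero solution for sample(s) "
                        f"{list(degenerate[degenerate].index)}; using uniform "
                        "conditional proportions",
                        UserWarning,
                        stacklevel=2,
                    )
            cond = cond.div(sums, axis=0)
            conditional[node] = cond
            nodes_meta[node] = est.metadata
            for leaf in leaves:
                leaf_cols[leaf] = cond[leaf] * layer1[group]
        props = pd.DataFrame({leaf: leaf_cols[leaf] for leaf in hierarchy.leaves})
        props[UNKNOWN] = layer1[UNKNOWN]
        return HiBEDResults(
            model=self,
            layer=2,
            proportions=props,
            layer1=layer1,
            conditional=conditional,
            metadata=nodes_meta,
        )


@dataclass
class HiBEDResults:
    """Fitted proportions plus per-node diagnostics.

    ``proportions`` holds the reported estimate (groups + unknown at layer
    1; the seven leaf types + unknown at layer 2, ordered GABA, GLU,
    Astrocyte, Microglia, Oligodendrocyte, Endothelial, Stromal, unknown
    for the default hierarchy). ``layer1`` and ``conditional`` expose the
    intermediate quantities of the three-step procedure.
    """

    model: HiBED
    layer: int
    proportions: pd.DataFrame
    layer1: pd.DataFrame
    conditional: dict[str, pd.DataFrame]
    metadata: dict

    def as_estimate(self) -> ProportionEstimate:
        return ProportionEstimate(
            values=self.proportions.copy(),
            layer=self.layer,
            metadata={"tool_version": _version, **self.metadata},
        )

    def to_csv(self, path) -> None:
        from .io import write_proportions

        write_proportions(self.proportions, path)

    def summary(self) -> str:
        lines = [
            f"HiBED deconvolution results (layer {self.layer})",
            f"samples: {len(self.proportions)}   "
            f"cell types: {', '.join(c for c in self.proportions.columns if c != UNKNOWN)}",
            "",
            "Mean proportions (+/- SD) across samples:",
        ]
        mean = self.proportions.mean(axis=0)
        sd = self.proportions.std(axis=0, ddof=1) if len(self.proportions) > 1 else mean * 0.0
        for ct in self.proportions.columns:
            lines.append(f"  {ct:<16s} {mean[ct]:7.4f} +/- {sd[ct]:.4f}")
        for node, meta in self.metadata.items():
            lines.append(
                f"node {node}: {meta['library_probes']} library probes, "
                f"sum_mode={meta['sum_mode']}"
            )
        return "\n".join(lines)


def hibed_deconvolve(
    bulk: BetaMatrix, lib: ReferenceLibrary, layer: int = 2, sum_mode: str = "le_one"
) -> ProportionEstimate:
    """Functional wrapper: fit the hierarchical model and return proportions."""
    return HiBED(bulk, lib).fit(layer=layer, sum_mode=sum_mode).as_estimate()
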
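"""Two-layer brain cell-type hierarchy.

The default hierarchy covers seven leaf cell types partitioned into three
Layer-1 groups: neuronal (GABAergic and glutamatergic neurons), glial
(astrocytes, microglia, oligodendrocytes) and endothelial/stromal cells.
One reference sub-library is attached to the Layer-1 node (discriminating
the groups) and one to each Layer-2 node with at least two leaves
(discriminating that group's leaf types).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._errors import ValidationError

LAYER1 = "Layer1"

# canonical leaf labels, in reporting order
GABA = "GABA"
GLU = "GLU"
ASTROCYTE = "Astrocyte"
MICROGLIA = "Microglia"
OLIGODENDROCYTE = "Oligodendrocyte"
ENDOTHELIAL = "Endothelial"
STROMAL = "Stromal"

DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "Neuronal": (GABA, GLU),
    "Glial": (ASTROCYTE, MICROGLIA, OLIGODENDROCYTE),
    "EndoStromal": (ENDOTHELIAL, STROMAL),
}

# node letters follow the published layout: 2A = endothelial/stromal,
# 2B = glial, 2C = neuronal
_DEFAULT_NODE_OF_GROUP = {"EndoStromal": "Layer2A", "Glial": "Layer2B", "Neuronal": "Layer2C"}


@dataclass(frozen=True)
class CellHierarchy:
    """Mapping from Layer-1 group labels to ordered leaf cell types.

    Leaves must partition (each leaf in exactly one group), with at least
    two nonempty groups.
    """

    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )

    def __post_init__(self) -> None:
        groups = {g: tuple(leaves) for g, leaves in self.groups.items()}
        object.__setattr__(self, "groups", groups)
        if len(groups) < 2:
            raise ValidationError("hierarchy needs at least 2 groups")
        seen: set[str] = set()
        for g, leaves in groups.items():
            if not leaves:
                raise ValidationError(f"group {g!r} is empty")
            for leaf in leaves:
                if leaf in seen:
                    raise ValidationError(f"leaf {leaf!r} appears in more than one group")
                seen.add(leaf)
        if seen & set(groups):
            raise ValidationError("group labels and leaf labels must be distinct")

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(self.groups)

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(leaf for leaves in self.groups.values() for leaf in leaves)

    def group_of(self, leaf: str) -> str:
        for g, leaves in self.groups.items():
            if leaf in leaves:
                return g
        raise ValidationError(f"unknown cell type {leaf!r}")

    def layer2_nodes(self) -> dict[str, str]:
        """Node label -> group label, for every group with >=2 leaves.

        Default group names keep the published letters (2A endo/stromal,
        2B glial, 2C neuronal); other hierarchies get letters in group order.
        """
        multi = [g for g, leaves in self.groups.items() if len(leaves) >= 2]
        if all(g in _DEFAULT_NODE_OF_GROUP for g in multi):
            items = sorted(
                ((_DEFAULT_NODE_OF_GROUP[g], g) for g in multi), key=lambda kv: kv[0]
            )
            return dict(items)
        letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        return {f"Layer2{letters[i]}": g for i, g in enumerate(multi)}

    def node_labels(self) -> tuple[str, ...]:
        return (LAYER1, *self.layer2_nodes())

    def to_dict(self) -> dict[str, list[str]]:
        return {g: list(leaves) for g, leaves in self.groups.items()}

    @classmethod
    def from_dict(cls, d: dict[str, list[str]]) -> "CellHierarchy":
        return cls(groups={g: tuple(v) for g, v in d.items()})


DEFAULT_HIERARCHY = CellHierarchy()
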
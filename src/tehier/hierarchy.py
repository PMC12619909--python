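"""The transposable-element class taxonomy as a rooted tree.

The taxonomy organises labels from the root ``TE`` down through classes
(retrotransposons vs DNA transposons), orders (LTR, LINE, SINE, TIR, ...)
and superfamilies (Gypsy, hAT, CACTA, ...).  One classifier is attached
to every *parent node* — an internal node with at least two children —
so the shipped default tree exposes nine classifier sites: TE, ClassI,
ClassII, LTR, nonLTR, LINE, SINE, ERV and TIR.

The exact child inventory below superfamily level varies between repeat
databases; the tree is therefore fully configuration-driven (a mapping
``node -> [children]``), with the default assembled from the standard
Wicker-style hierarchy.  Labels match case-sensitively after whitespace
trimming; an optional alias table maps header variants (e.g. ``MITE``)
onto canonical labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["Taxonomy", "load_taxonomy", "DEFAULT_TAXONOMY"]

#: Default tree: node -> children.  Nine internal nodes have >= 2 children.
DEFAULT_TAXONOMY: dict[str, list[str]] = {
    "TE": ["ClassI", "ClassII"],
    "ClassI": ["LTR", "nonLTR"],
    "LTR": ["Copia", "Gypsy", "Bel-Pao", "ERV"],
    "ERV": ["ERV1", "ERV2", "ERV3"],
    "nonLTR": ["LINE", "SINE"],
    "LINE": ["L1", "CR1", "RTE", "Rex1", "Jockey", "I"],
    "SINE": ["SINE1/7SL", "SINE2/tRNA", "SINE3/5S", "ID"],
    "ClassII": ["TIR", "Helitron", "Maverick"],
    "TIR": ["hAT", "TcMar", "MULE", "PIF", "CACTA", "Merlin", "P"],
}


class TaxonomyError(ValueError):
    """Raised when a taxonomy configuration fails validation."""


@dataclass(frozen=True)
class Taxonomy:
    """A validated rooted tree over label strings.

    Attributes
    ----------
    root : str
    parent : dict
        child -> parent mapping (the root has no entry).
    children : dict
        node -> ordered list of children (insertion order of the config).
    aliases : dict
        alias -> canonical label.
    """

    root: str
    parent: dict[str, str]
    children: dict[str, list[str]]
    aliases: dict[str, str] = field(default_factory=dict)

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return {self.root} | set(self.parent)

    def resolve(self, label: str) -> str:
        """Canonical node name for `label` (trimmed, alias-resolved)."""
        label = label.strip()
        label = self.aliases.get(label, label)
        if label != self.root and label not in self.parent:
            raise KeyError(f"unknown taxonomy label {label!r}")
        return label

    def ancestors(self, label: str) -> list[str]:
        """Root-first path of labels ending at `label`."""
        label = self.resolve(label)
        path = [label]
        while label != self.root:
            label = self.parent[label]
            path.append(label)
        return path[::-1]

    def leaves(self) -> list[str]:
        return [n for n in self._preorder() if not self.children.get(n)]

    def parent_nodes(self) -> list[str]:
        """Internal nodes with >= 2 children — the classifier sites.

        Deterministic order: pre-order traversal with children visited in
        lexicographic order.
        """
        return [n for n in self._preorder() if len(self.children.get(n, [])) >= 2]

    def _preorder(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(sorted(self.children.get(node, []), reverse=True))
        return out

    def depth(self, label: str) -> int:
        return len(self.ancestors(label)) - 1

    # -- serialization ------------------------------------------------------

    def to_edges(self) -> str:
        """Plain-text serialization, one ``child<TAB>parent`` line per edge."""
        lines = []
        for node in self._preorder():
            for child in sorted(self.children.get(node, [])):
                lines.append(f"{child}\t{node}")
        return "\n".join(lines) + "\n"

    def to_config(self) -> dict:
        return {
            "root": self.root,
            "children": {n: list(c) for n, c in self.children.items() if c},
            "aliases": dict(self.aliases),
        }


def _validate(children: dict[str, list[str]], root: str,
              aliases: dict[str, str]) -> Taxonomy:
    parent: dict[str, str] = {}
    for node, kids in children.items():
        for kid in kids:
            if kid == node:
                raise TaxonomyError(f"cycle: node {kid!r} lists itself as parent")
            if kid in parent:
                raise TaxonomyError(
                    f"duplicate label: {kid!r} has parents {parent[kid]!r} and {node!r}"
                )
            parent[kid] = node
    if root in parent:
        raise TaxonomyError(f"cycle: root {root!r} appears as a child")
    all_nodes = {root} | set(parent)
    for node in children:
        if node not in all_nodes:
            raise TaxonomyError(f"orphan node: {node!r} has children but no parent and is not the root")
    # cycle / connectivity check by walking each node up to the root
    for node in parent:
        seen = {node}
        cur = node
        while cur != root:
            cur = parent.get(cur)
            if cur is None:
                raise TaxonomyError(f"orphan node: {node!r} does not reach the root")
            if cur in seen:
                raise TaxonomyError(f"cycle involving node {cur!r}")
            seen.add(cur)
    for alias, target in aliases.items():
        if target not in all_nodes:
            raise TaxonomyError(f"alias {alias!r} points at unknown node {target!r}")
    return Taxonomy(root=root, parent=parent,
                    children={n: list(c) for n, c in children.items()},
                    aliases={a.strip(): t for a, t in aliases.items()})


def load_taxonomy(config: dict | str | None = None) -> Taxonomy:
    """Build and validate a Taxonomy.

    Parameters
    ----------
    config
        ``None`` for the shipped default tree; a path to a YAML file; or
        a mapping.  The mapping form is either ``{node: [children], ...}``
        directly, or ``{"root": ..., "children": {...}, "aliases": {...}}``.
    """
    if config is None:
        return _validate(DEFAULT_TAXONOMY, "TE", {"MITE": "TIR"})
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict) or not config:
        raise TaxonomyError("taxonomy config must be a non-empty mapping")
    if "children" in config:
        children = {str(k).strip(): [str(c).strip() for c in (v or [])]
                    for k, v in config["children"].items()}
        aliases = {str(k): str(v) for k, v in (config.get("aliases") or {}).items()}
        root = config.get("root")
    else:
        children = {str(k).strip(): [str(c).strip() for c in (v or [])]
                    for k, v in config.items()}
        aliases = {}
        root = None
    if root is None:
        as_child = {c for kids in children.values() for c in kids}
        roots = [n for n in children if n not in as_child]
        if len(roots) != 1:
            raise TaxonomyError(f"missing root: expected exactly one top node, found {roots!r}")
        root = roots[0]
    return _validate(children, str(root).strip(), aliases)
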
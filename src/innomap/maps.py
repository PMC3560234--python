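"""Concept maps: rooted labeled trees for the three description axes.

For each indication of a product three maps are built — the medical context
of use, the nature of the novelty, and the impact versus a comparator — and
serialized to FreeMind mind-map XML (``.mm``), Graphviz DOT, or canonical
JSON.

Color conventions: elements specific to the new product are highlighted blue;
impact verdicts are colored green (positive), yellow (equivalent) and red
(negative); not-assessable items stay uncolored.  The novelty map always
renders the full aspect taxonomy and uses the highlight alone to show the
drug, so maps of different drugs are visually comparable.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .model import (
    ContractError,
    Indication,
    ProductRecord,
    TherapeuticArsenal,
    normalize_term,
)
from .novelty import NoveltyProfile
from .impact import ImpactProfile
from .schemas import ParseError

__all__ = [
    "AXES",
    "COLOR_BY_HIGHLIGHT",
    "ConceptMap",
    "ConceptMapNode",
    "HIGHLIGHTS",
    "build_context_map",
    "build_impact_map",
    "build_novelty_map",
    "export_dot",
    "export_freemind",
    "import_freemind",
    "map_from_document",
    "map_to_document",
]

AXES = ("context", "novelty", "impact")
HIGHLIGHTS = ("none", "product_specific", "positive", "equivalent", "negative")

# Fixed rendering palette (6-digit hex, FreeMind BACKGROUND_COLOR).
COLOR_BY_HIGHLIGHT = {
    "product_specific": "#99CCFF",  # blue
    "positive": "#99FF99",  # green
    "equivalent": "#FFFF99",  # yellow
    "negative": "#FF9999",  # red
}
_HIGHLIGHT_BY_COLOR = {v: k for k, v in COLOR_BY_HIGHLIGHT.items()}


@dataclass
class ConceptMapNode:
    label: str
    children: list["ConceptMapNode"] = field(default_factory=list)
    highlight: str = "none"

    def __post_init__(self):
        if not self.label:
            raise ValueError("node labels must be non-empty")
        if self.highlight not in HIGHLIGHTS:
            raise ValueError(f"highlight must be one of {HIGHLIGHTS}")

    def add(self, label: str, highlight: str = "none") -> "ConceptMapNode":
        child = ConceptMapNode(label=label, highlight=highlight)
        self.children.append(child)
        return child

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def size(self) -> int:
        return sum(1 for _ in self.walk())


@dataclass
class ConceptMap:
    axis: str  # context | novelty | impact
    indication_term: str
    root: ConceptMapNode

    def __post_init__(self):
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")


# ---------------------------------------------------------------------------
# Builders


def _composition_label(product: ProductRecord) -> str:
    parts = []
    for s in product.substances:
        if s.strength_value is not None:
            parts.append(f"{s.inn_name} {s.strength_value:g} {s.strength_unit}")
        else:
            parts.append(s.inn_name)
    return ", ".join(parts)


def build_context_map(
    product: ProductRecord,
    indication: Indication,
    arsenal: TherapeuticArsenal,
) -> ConceptMap:
    """Medical context of use for one indication.

    Root is the condition; branches describe the treatment target and type,
    required co-administrations, the new product itself (blue), and the
    therapeutic arsenal grouped by pharmacotherapeutic group with one leaf
    per member.
    """
    if normalize_term(indication.condition_term) not in product.indication_terms():
        raise ContractError(
            f"indication {indication.condition_term!r} is not on product "
            f"{product.brand_name!r}"
        )
    root = ConceptMapNode(label=indication.condition_term)
    root.add("treatment target").add(indication.target_kind)
    root.add("treatment type").add(indication.treatment_type)
    coad = root.add("co-administration")
    for term in sorted(indication.coadministration_terms):
        coad.add(term, highlight="product_specific")
    new = root.add("new product", highlight="product_specific")
    new.add(product.brand_name, highlight="product_specific")
    new.add(_composition_label(product), highlight="product_specific")
    new.add(product.pharmaceutical_form, highlight="product_specific")
    for route in sorted(product.routes):
        new.add(route, highlight="product_specific")
    ars = root.add("therapeutic arsenal")
    groups: dict[str, list[ProductRecord]] = {}
    for m in arsenal.members:
        groups.setdefault(normalize_term(m.pharmacotherapeutic_group), []).append(m)
    for group in sorted(groups):
        gnode = ars.add(group or "ungrouped")
        for m in sorted(groups[group], key=lambda m: m.brand_name):
            gnode.add(m.brand_name)
    return ConceptMap(
        axis="context", indication_term=indication.condition_term, root=root
    )


# label of the taxonomy node carrying each novelty flag
_NOVELTY_FLAG_LABELS = {
    "new_mechanism_of_action": "new mechanism of action",
    "new_pharmacotherapeutic_group": "new pharmacotherapeutic group",
    "known_combination_new_form": "known combination in a new form",
    "new_route.for_molecule": "route: new for the molecule",
    "new_route.for_arsenal": "route: new for the arsenal",
    "new_form.for_molecule": "form: new for the molecule",
    "new_form.for_route": "form: new for the route",
    "new_form.for_arsenal": "form: new for the arsenal",
    "new_dose": "new dose",
    "new_presentation": "new presentation",
    "new_protocol": "new protocol",
    "new_indication_or_extension": "new indication or extension",
}
_TOP_LEVEL_LABELS = {
    "new_molecule": "new molecule",
    "new_combination": "new combination of molecules",
    "known_molecule": "known molecule",
}


def build_novelty_map(
    profile: NoveltyProfile, indication_term: str = "novelty"
) -> ConceptMap:
    """Full novelty taxonomy with the product's true aspects highlighted.

    False branches are retained unhighlighted: the skeleton shows the
    taxonomy, the coloring shows the drug.
    """

    def hl(flag: str) -> str:
        return "product_specific" if profile.flags()[flag] else "none"

    root = ConceptMapNode(label="nature of the novelty")
    top = root.add("top-level category")
    for cat, label in _TOP_LEVEL_LABELS.items():
        top.add(
            label,
            highlight="product_specific" if profile.top_level == cat else "none",
        )
    pharm = root.add("pharmacology")
    pharm.add(
        _NOVELTY_FLAG_LABELS["new_mechanism_of_action"], hl("new_mechanism_of_action")
    )
    pharm.add(
        _NOVELTY_FLAG_LABELS["new_pharmacotherapeutic_group"],
        hl("new_pharmacotherapeutic_group"),
    )
    comb = root.add("combination")
    comb.add(
        _NOVELTY_FLAG_LABELS["known_combination_new_form"],
        hl("known_combination_new_form"),
    )
    usage = root.add("usage")
    route = usage.add("new route of administration")
    route.add(_NOVELTY_FLAG_LABELS["new_route.for_molecule"], hl("new_route.for_molecule"))
    route.add(_NOVELTY_FLAG_LABELS["new_route.for_arsenal"], hl("new_route.for_arsenal"))
    form = usage.add("new pharmaceutical form")
    form.add(_NOVELTY_FLAG_LABELS["new_form.for_molecule"], hl("new_form.for_molecule"))
    form.add(_NOVELTY_FLAG_LABELS["new_form.for_route"], hl("new_form.for_route"))
    form.add(_NOVELTY_FLAG_LABELS["new_form.for_arsenal"], hl("new_form.for_arsenal"))
    usage.add(_NOVELTY_FLAG_LABELS["new_dose"], hl("new_dose"))
    usage.add(_NOVELTY_FLAG_LABELS["new_presentation"], hl("new_presentation"))
    usage.add(_NOVELTY_FLAG_LABELS["new_protocol"], hl("new_protocol"))
    reg = root.add("regulatory")
    reg.add(
        _NOVELTY_FLAG_LABELS["new_indication_or_extension"],
        hl("new_indication_or_extension"),
    )
    return ConceptMap(axis="novelty", indication_term=indication_term, root=root)


def build_impact_map(
    profile: ImpactProfile, indication_term: str = "impact"
) -> ConceptMap:
    """Impact map: one branch per dimension, one leaf per item, colored by
    verdict (not-assessable leaves uncolored)."""
    verdict_highlight = {
        "positive": "positive",
        "equivalent": "equivalent",
        "negative": "negative",
        "not_assessable": "none",
    }
    root = ConceptMapNode(label=f"impact versus {profile.comparator_ref}")
    for dim in ("efficacy", "safety", "ease_of_use"):
        branch = root.add(dim.replace("_", " "))
        for item in profile.items:
            if item.dimension != dim:
                continue
            branch.add(
                f"{item.subcategory}: {item.item_term}",
                highlight=verdict_highlight[item.verdict],
            )
        branch.add(f"summary: {profile.dimension_summaries.get(dim, 'impact')}")
    return ConceptMap(axis="impact", indication_term=indication_term, root=root)


# ---------------------------------------------------------------------------
# FreeMind (.mm) serialization


def export_freemind(cmap: ConceptMap) -> str:
    """Serialize to FreeMind mind-map XML (dialect pinned to map version
    1.0.1); highlights become BACKGROUND_COLOR attributes."""

    def fill(el: ET.Element, node: ConceptMapNode) -> None:
        attrs = {"TEXT": node.label}
        color = COLOR_BY_HIGHLIGHT.get(node.highlight)
        if color:
            attrs["BACKGROUND_COLOR"] = color
        child_el = ET.SubElement(el, "node", attrs)
        for child in node.children:
            fill(child_el, child)

    map_el = ET.Element(
        "map", {"version": "1.0.1", "AXIS": cmap.axis, "INDICATION": cmap.indication_term}
    )
    fill(map_el, cmap.root)
    ET.indent(map_el)
    return ET.tostring(map_el, encoding="unicode", xml_declaration=True) + "\n"


def import_freemind(document: str) -> ConceptMap:
    """Parse FreeMind XML back into a :class:`ConceptMap`; inverse of
    :func:`export_freemind` on label, child order and highlight."""
    try:
        map_el = ET.fromstring(document)
    except ET.ParseError as exc:
        raise ParseError("$", f"malformed mind-map XML: {exc}") from exc
    if map_el.tag != "map":
        raise ParseError("$", f"expected <map> root, found <{map_el.tag}>")
    nodes = [el for el in map_el if el.tag == "node"]
    if len(nodes) != 1:
        raise ParseError("$.map", "expected exactly one root <node>")

    def build(el: ET.Element) -> ConceptMapNode:
        label = el.get("TEXT")
        if not label:
            raise ParseError("$.node", "node element lacks a TEXT attribute")
        color = el.get("BACKGROUND_COLOR")
        highlight = "none"
        if color is not None:
            highlight = _HIGHLIGHT_BY_COLOR.get(color.upper())
            if highlight is None:
                raise ParseError("$.node", f"unknown BACKGROUND_COLOR {color!r}")
        node = ConceptMapNode(label=label, highlight=highlight)
        node.children = [build(c) for c in el if c.tag == "node"]
        return node

    axis = map_el.get("AXIS", "context")
    indication = map_el.get("INDICATION", "")
    return ConceptMap(
        axis=axis if axis in AXES else "context",
        indication_term=indication,
        root=build(nodes[0]),
    )


# ---------------------------------------------------------------------------
# DOT serialization

_DOT_ESCAPE = re.compile(r'(["\\])')


def _dot_quote(text: str) -> str:
    return '"' + _DOT_ESCAPE.sub(r"\\\1", text) + '"'


def export_dot(cmap: ConceptMap) -> str:
    """Serialize to a Graphviz DOT digraph: one node per tree node, one edge
    per parent-child pair (edge count = node count - 1), fillcolor per
    highlight."""
    lines = ["digraph conceptmap {", "  rankdir=LR;", '  node [shape=box];']
    ids: dict[int, str] = {}
    for i, node in enumerate(cmap.root.walk()):
        ids[id(node)] = f"n{i}"
        attrs = [f"label={_dot_quote(node.label)}"]
        color = COLOR_BY_HIGHLIGHT.get(node.highlight)
        if color:
            attrs.append('style=filled')
            attrs.append(f'fillcolor="{color}"')
        lines.append(f"  n{i} [{', '.join(attrs)}];")
    for node in cmap.root.walk():
        for child in node.children:
            lines.append(f"  {ids[id(node)]} -> {ids[id(child)]};")
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JSON document form


def _node_doc(node: ConceptMapNode) -> dict:
    return {
        "label": node.label,
        "highlight": node.highlight,
        "children": [_node_doc(c) for c in node.children],
    }


def map_to_document(cmap: ConceptMap) -> dict:
    return {
        "axis": cmap.axis,
        "indication_term": cmap.indication_term,
        "root": _node_doc(cmap.root),
    }


def map_from_document(document: dict) -> ConceptMap:
    def build(doc: dict) -> ConceptMapNode:
        node = ConceptMapNode(
            label=doc["label"], highlight=doc.get("highlight", "none")
        )
        node.children = [build(c) for c in doc.get("children", [])]
        return node

    return ConceptMap(
        axis=document["axis"],
        indication_term=document["indication_term"],
        root=build(document["root"]),
    )
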
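"""Symbolic rule extraction from interval temporal decision trees.

Every root-to-leaf path of a tree is a conjunction of interval-modal
atoms: a left edge through split <R>(p) contributes the existential atom
``<R>(p)`` ("some R-related interval satisfies p"), a right edge
contributes its universal dual ``[R](not p)`` ("every R-related interval
violates p"), with the negation folded into the comparator (not(f >= c)
is rendered f < c).  Merging the paths of same-label leaves with
disjunction yields exactly one rule per class, and the merged rules
partition the instance space: rule-based prediction coincides with tree
prediction on every instance.

Atoms in a conjunction are evaluated left to right with the tree's
reference-interval semantics: a satisfied existential atom moves the
reference interval to its witness; universal atoms leave it unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .measures import FeatureTriple
from .temporal_forest import (
    Interval,
    Leaf,
    Node,
    Proposition,
    TemporalDataset,
    TemporalTree,
    eval_split,
    TemporalSplit,
)

__all__ = ["RuleAtom", "TemporalRule", "extract_rules", "render_rule",
           "parse_rule", "rule_predict"]

_UNI = {"lang": "⟨", "rang": "⟩", "and": " ∧ ", "or": " ∨ ",
        "geq": "≥", "lt": "<", "implies": " ⇒ ", "true": "⊤"}
_ASCII = {"lang": "<", "rang": ">", "and": " & ", "or": " | ",
          "geq": ">=", "lt": "<", "implies": " => ", "true": "TRUE"}

_REL_UNICODE = {"Abar": "Ā", "Lbar": "L̄", "Bbar": "B̄",
                "Ebar": "Ē", "Dbar": "D̄", "Obar": "Ō"}
_REL_ASCII = {"Abar": "A~", "Lbar": "L~", "Bbar": "B~",
              "Ebar": "E~", "Dbar": "D~", "Obar": "O~"}


@dataclass(frozen=True)
class RuleAtom:
    modality: str  # 'existential' or 'universal'
    relation: str
    proposition: Proposition


@dataclass(frozen=True)
class TemporalRule:
    label: str
    body: tuple[tuple[RuleAtom, ...], ...]  # disjunction of conjunctions


def _negate(p: Proposition) -> Proposition:
    return Proposition(p.feature, "<" if p.comparator == ">=" else ">=", p.threshold)


def extract_rules(tree: TemporalTree, merge_per_class: bool = True) -> list[TemporalRule]:
    """One conjunction per leaf path; merged per class label by default."""
    paths: list[tuple[str, tuple[RuleAtom, ...]]] = []

    def walk(node, atoms):
        if isinstance(node, Leaf):
            paths.append((node.label, tuple(atoms)))
            return
        s: TemporalSplit = node.split
        walk(node.left, atoms + [RuleAtom("existential", s.relation, s.proposition)])
        walk(node.right, atoms + [RuleAtom("universal", s.relation, _negate(s.proposition))])

    walk(tree.root, [])
    if not merge_per_class:
        return [TemporalRule(lab, (conj,)) for lab, conj in paths]
    by_label: dict[str, list] = {}
    for lab, conj in paths:
        by_label.setdefault(lab, []).append(conj)
    return [TemporalRule(lab, tuple(conjs)) for lab, conjs in by_label.items()]


# ---------------------------------------------------------------------------
# rendering and parsing
# ---------------------------------------------------------------------------


def _render_rel(rel: str, ascii_only: bool) -> str:
    table = _REL_ASCII if ascii_only else _REL_UNICODE
    return table.get(rel, rel)


def _render_atom(atom: RuleAtom, t: dict, ascii_only: bool) -> str:
    p = atom.proposition
    rel = _render_rel(atom.relation, ascii_only)
    mod = f"{t['lang']}{rel}{t['rang']}" if atom.modality == "existential" else f"[{rel}]"
    cmp_ = t["geq"] if p.comparator == ">=" else t["lt"]
    thr = repr(p.threshold)
    return f"{mod}({p.feature.measure}({p.feature.electrode} F{p.feature.band}){cmp_}{thr})"


def render_rule(rule: TemporalRule, ascii_only: bool = False) -> str:
    """Text form, e.g. ``<L>(Z10(E4 F10)>=0.5) & [L](Z10(E5 F11)<0.81) => like``."""
    t = _ASCII if ascii_only else _UNI
    conjs = []
    for conj in rule.body:
        if not conj:
            conjs.append(t["true"])
        else:
            conjs.append(t["and"].join(_render_atom(a, t, ascii_only) for a in conj))
    body = t["or"].join(conjs)
    return f"{body}{t['implies']}{rule.label}"


_ATOM_RE = re.compile(
    r"(?P<mod>⟨|\[|<)(?P<rel>[ALBEDO](?:̄|~)?|=)(?:⟩|\]|>)"
    r"\((?P<meas>[A-Z0-9]+)\((?P<elec>\S+) F(?P<band>\d+)\)"
    r"(?P<cmp>≥|>=|<)(?P<thr>[^)]+)\)"
)


def _parse_rel(s: str) -> str:
    if len(s) == 2:
        return s[0] + "bar"
    return s


def parse_rule(text: str) -> TemporalRule:
    """Inverse of :func:`render_rule` (accepts both unicode and ASCII forms)."""
    text = text.strip()
    m = re.search(r"(⇒|=>)", text)
    if not m:
        raise ValueError("rule has no implication")
    body_text, label = text[: m.start()].strip(), text[m.end() :].strip()
    conjs = []
    for conj_text in re.split(r"∨|\|", body_text):
        conj_text = conj_text.strip()
        if conj_text in ("⊤", "TRUE"):
            conjs.append(())
            continue
        atoms = []
        for am in _ATOM_RE.finditer(conj_text):
            modality = "universal" if am.group("mod") == "[" else "existential"
            prop = Proposition(
                FeatureTriple(am.group("elec"), int(am.group("band")), am.group("meas")),
                ">=" if am.group("cmp") in (">=", "≥") else "<",
                float(am.group("thr")),
            )
            atoms.append(RuleAtom(modality, _parse_rel(am.group("rel")), prop))
        if not atoms:
            raise ValueError(f"unparseable conjunction: {conj_text!r}")
        conjs.append(tuple(atoms))
    return TemporalRule(label, tuple(conjs))


# ---------------------------------------------------------------------------
# rule-based prediction
# ---------------------------------------------------------------------------


def _conj_holds(conj, values_by_feature, dataset: TemporalDataset) -> bool:
    current = Interval(1, 2)
    for atom in conj:
        feat_vals = values_by_feature(atom.proposition.feature)
        if atom.modality == "existential":
            split = TemporalSplit(atom.relation, atom.proposition)
            branch, witness = eval_split(feat_vals, split, current, dataset)
            if branch == "right":
                return False
            current = witness
        else:
            # [R](p) holds iff no accessible interval satisfies not-p
            split = TemporalSplit(atom.relation, _negate(atom.proposition))
            branch, _ = eval_split(feat_vals, split, current, dataset)
            if branch == "left":
                return False
    return True


def rule_predict(rules, dataset: TemporalDataset, indices=None) -> np.ndarray:
    """Classify instances with merged rules; exactly one class rule should fire
    per instance when the rules come from a single tree."""
    idx = np.arange(dataset.n_instances) if indices is None else np.asarray(list(indices))
    feat_pos = {f: j for j, f in enumerate(dataset.features)}

    out = []
    for i in idx:
        def lookup(feature, _i=i):
            j = feat_pos.get(feature)
            if j is None:
                raise KeyError(f"instance lacks feature {feature}")
            return dataset.M[_i, j, :]

        fired = [r.label for r in rules
                 if any(_conj_holds(conj, lookup, dataset) for conj in r.body)]
        if len(fired) != 1:
            raise ValueError(
                f"expected exactly one rule to fire for instance {i}, got {fired}"
            )
        out.append(fired[0])
    return np.array(out)
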
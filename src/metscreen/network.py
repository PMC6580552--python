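"""Pathway-annotated metabolic reaction networks.

The simulator operates on a bipartite component/reaction network in which
every component (gene, protein, compound, ...) belongs to one or more
pathways; pathway crosstalk is represented purely as overlapping membership
sets.  The native serialization is a small versioned JSON dialect; SBML
Level 3 files (with the Groups package or note tags carrying pathway
membership) can be imported.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

COMPONENT_KINDS = ("gene", "protein", "compound", "other")
LAW_TYPES = ("mass_action", "unit")

SCHEMA_VERSION = 1


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed under the named format."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates structural invariants."""

    def __init__(self, violations: Sequence["Violation"]):
        self.violations = list(violations)
        lines = "\n".join(f"  - {v}" for v in self.violations)
        super().__init__(f"model failed validation ({len(self.violations)} violation(s)):\n{lines}")


@dataclass(frozen=True)
class Component:
    """A network node: gene, protein, compound or other entity."""

    id: str
    name: str = ""
    kind: str = "other"
    pathways: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.name:
            object.__setattr__(self, "name", self.id)
        object.__setattr__(self, "pathways", frozenset(self.pathways))


@dataclass(frozen=True)
class ReactionParticipant:
    """A (component, role) pair; role is the stoichiometric weight/exponent."""

    component_id: str
    role: float = 1.0


@dataclass(frozen=True)
class KineticLaw:
    """Multiplicative rate term of a reaction.

    ``unit`` is the rate-constant-1 special case of ``mass_action``.
    """

    law_type: str = "mass_action"
    rate_constant: float = 1.0

    def effective_rate(self) -> float:
        return 1.0 if self.law_type == "unit" else self.rate_constant


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: tuple[ReactionParticipant, ...] = ()
    products: tuple[ReactionParticipant, ...] = ()
    law: KineticLaw = field(default_factory=KineticLaw)
    pathways: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        object.__setattr__(self, "pathways", frozenset(self.pathways))


@dataclass(frozen=True)
class Pathway:
    id: str
    name: str = ""
    pathway_class: str | None = None  # e.g. "metabolic" / "signaling", if known

    def __post_init__(self):
        if not self.name:
            object.__setattr__(self, "name", self.id)


@dataclass
class MetabolicModel:
    """Components, reactions and the pathway vocabulary they reference."""

    components: tuple[Component, ...] = ()
    reactions: tuple[Reaction, ...] = ()
    pathways: tuple[Pathway, ...] = ()

    def __post_init__(self):
        self.components = tuple(self.components)
        self.reactions = tuple(self.reactions)
        self.pathways = tuple(self.pathways)

    @property
    def component_index(self) -> dict[str, Component]:
        return {c.id: c for c in self.components}

    @property
    def pathway_ids(self) -> set[str]:
        return {p.id for p in self.pathways}

    def genes(self) -> list[Component]:
        return [c for c in self.components if c.kind == "gene"]


@dataclass(frozen=True)
class Violation:
    """One invariant violation; validation reports are data, not exceptions."""

    kind: str
    subject: str
    message: str

    def __str__(self) -> str:
        return f"[{self.kind}] {self.subject}: {self.message}"


def validate_model(model: MetabolicModel) -> list[Violation]:
    """Check every structural invariant; an empty list means the model is valid."""
    out: list[Violation] = []
    comp_ids: set[str] = set()
    pw_ids = model.pathway_ids

    dup_c = [i for i, n in Counter(c.id for c in model.components).items() if n > 1]
    for i in dup_c:
        out.append(Violation("duplicate_component", i, "component id appears more than once"))
    dup_r = [i for i, n in Counter(r.id for r in model.reactions).items() if n > 1]
    for i in dup_r:
        out.append(Violation("duplicate_reaction", i, "reaction id appears more than once"))
    dup_p = [i for i, n in Counter(p.id for p in model.pathways).items() if n > 1]
    for i in dup_p:
        out.append(Violation("duplicate_pathway", i, "pathway id appears more than once"))

    for c in model.components:
        comp_ids.add(c.id)
        if c.kind not in COMPONENT_KINDS:
            out.append(Violation("bad_kind", c.id, f"unknown component kind {c.kind!r}"))
        if not c.pathways:
            out.append(Violation("pathway_membership", c.id, "component belongs to no pathway"))
        for p in c.pathways - pw_ids:
            out.append(Violation("unknown_pathway", c.id, f"references undefined pathway {p!r}"))

    for r in model.reactions:
        if not r.reactants:
            out.append(Violation("empty_reactants", r.id, "reaction has no reactants"))
        if not r.products:
            out.append(Violation("empty_products", r.id, "reaction has no products"))
        if r.law.law_type not in LAW_TYPES:
            out.append(Violation("bad_law", r.id, f"unknown kinetic law {r.law.law_type!r}"))
        if r.law.rate_constant < 0:
            out.append(Violation("bad_rate", r.id, f"rate constant {r.law.rate_constant} < 0"))
        for part in (*r.reactants, *r.products):
            if part.role <= 0:
                out.append(Violation("bad_role", r.id, f"{part.component_id} has role {part.role} <= 0"))
            if part.component_id not in comp_ids:
                out.append(
                    Violation("broken_reference", r.id, f"references missing component {part.component_id!r}")
                )
        for p in r.pathways - pw_ids:
            out.append(Violation("unknown_pathway", r.id, f"references undefined pathway {p!r}"))

    return out


@dataclass(frozen=True)
class ModelSummary:
    n_components: int
    n_components_by_kind: dict[str, int]
    n_reactions: int
    n_pathways: int
    pathway_sizes: dict[str, int]


def model_summary(model: MetabolicModel) -> ModelSummary:
    """Exact counts; a component in k pathways is counted in each of the k sizes."""
    by_kind = Counter(c.kind for c in model.components)
    sizes = {p.id: 0 for p in model.pathways}
    for c in model.components:
        for p in c.pathways:
            if p in sizes:
                sizes[p] += 1
    return ModelSummary(
        n_components=len(model.components),
        n_components_by_kind=dict(by_kind),
        n_reactions=len(model.reactions),
        n_pathways=len(model.pathways),
        pathway_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# native JSON dialect


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "pathways": [
            {"id": p.id, "name": p.name, **({"class": p.pathway_class} if p.pathway_class else {})}
            for p in model.pathways
        ],
        "components": [
            {"id": c.id, "name": c.name, "kind": c.kind, "pathways": sorted(c.pathways)}
            for c in model.components
        ],
        "reactions": [
            {
                "id": r.id,
                "reactants": [{"component": q.component_id, "role": q.role} for q in r.reactants],
                "products": [{"component": q.component_id, "role": q.role} for q in r.products],
                "law": {"type": r.law.law_type, "k": r.law.rate_constant},
                "pathways": sorted(r.pathways),
            }
            for r in model.reactions
        ],
    }


def model_from_dict(data: Mapping) -> MetabolicModel:
    try:
        pathways = tuple(
            Pathway(p["id"], p.get("name", ""), p.get("class")) for p in data.get("pathways", [])
        )
        components = tuple(
            Component(c["id"], c.get("name", ""), c.get("kind", "other"), frozenset(c.get("pathways", ())))
            for c in data.get("components", [])
        )
        reactions = tuple(
            Reaction(
                r["id"],
                tuple(ReactionParticipant(q["component"], q.get("role", 1.0)) for q in r.get("reactants", [])),
                tuple(ReactionParticipant(q["component"], q.get("role", 1.0)) for q in r.get("products", [])),
                KineticLaw(r.get("law", {}).get("type", "mass_action"), r.get("law", {}).get("k", 1.0)),
                frozenset(r.get("pathways", ())),
            )
            for r in data.get("reactions", [])
        )
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"malformed model dictionary: {exc!r}") from exc
    return MetabolicModel(components, reactions, pathways)


def save_model(model: MetabolicModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1) + "\n")


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from JSON (native) or SBML L3; validates before returning.

    ``format`` is inferred from the extension when not given (.xml/.sbml -> sbml).
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
        model = model_from_dict(data)
    elif format == "sbml":
        model = _read_sbml(path)
    else:
        raise ValueError(f"unknown model format {format!r}")
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)
    return model


# ---------------------------------------------------------------------------
# SBML import

_KIND_TOKENS = {k: k for k in COMPONENT_KINDS}


def _notes_fields(sbase) -> dict[str, str]:
    """Pull simple ``key: value`` lines out of an SBML notes block."""
    if not sbase.isSetNotes():
        return {}
    import libsbml

    text = libsbml.XMLNode.convertXMLNodeToString(sbase.getNotes())
    fields = {}
    for raw in text.replace("<", " <").split("\n"):
        line = raw
        for tag in ("<p>", "</p>", "<body>", "</body>", "<notes>", "</notes>"):
            line = line.replace(tag, " ")
        # strip any leftover xml tags crudely; notes here carry plain key: value lines
        while "<" in line and ">" in line:
            a, b = line.index("<"), line.index(">")
            if b < a:
                break
            line = line[:a] + " " + line[b + 1 :]
        if ":" in line:
            key, _, val = line.partition(":")
            fields[key.strip().lower()] = val.strip()
    return fields


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ModelFormatError(f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"{path}: SBML document contains no model")

    # pathway membership from the Groups package when present
    membership: dict[str, set[str]] = {}
    pathways: list[Pathway] = []
    groups_plug = sbml_model.getPlugin("groups")
    if groups_plug is not None:
        for gi in range(groups_plug.getNumGroups()):
            g = groups_plug.getGroup(gi)
            pathways.append(Pathway(g.getId(), g.getName() or g.getId()))
            for mi in range(g.getNumMembers()):
                ref = g.getMember(mi).getIdRef()
                membership.setdefault(ref, set()).add(g.getId())

    components = []
    for si in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(si)
        notes = _notes_fields(s)
        pw = set(membership.get(s.getId(), set()))
        if "pathways" in notes:
            pw |= {t.strip() for t in notes["pathways"].split(";") if t.strip()}
        kind = _KIND_TOKENS.get(notes.get("kind", "").lower(), "other")
        components.append(Component(s.getId(), s.getName() or s.getId(), kind, frozenset(pw)))

    reactions = []
    for ri in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(ri)
        reactants = tuple(
            ReactionParticipant(
                r.getReactant(i).getSpecies(),
                r.getReactant(i).getStoichiometry() if r.getReactant(i).isSetStoichiometry() else 1.0,
            )
            for i in range(r.getNumReactants())
        )
        products = tuple(
            ReactionParticipant(
                r.getProduct(i).getSpecies(),
                r.getProduct(i).getStoichiometry() if r.getProduct(i).isSetStoichiometry() else 1.0,
            )
            for i in range(r.getNumProducts())
        )
        k = 1.0
        if r.isSetKineticLaw():
            kl = r.getKineticLaw()
            for pi in range(kl.getNumLocalParameters()):
                lp = kl.getLocalParameter(pi)
                if lp.getId() == "k":
                    k = lp.getValue()
        pw = set(membership.get(r.getId(), set()))
        if not pw:  # fall back to the union of participant memberships
            idx = {c.id: c for c in components}
            for part in (*reactants, *products):
                if part.component_id in idx:
                    pw |= set(idx[part.component_id].pathways)
        reactions.append(Reaction(r.getId(), reactants, products, KineticLaw("mass_action", k), frozenset(pw)))

    known = {p.id for p in pathways}
    extra = sorted(
        {pid for c in components for pid in c.pathways if pid not in known}
        | {pid for r in reactions for pid in r.pathways if pid not in known}
    )
    pathways.extend(Pathway(pid) for pid in extra)
    return MetabolicModel(tuple(components), tuple(reactions), tuple(pathways))
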
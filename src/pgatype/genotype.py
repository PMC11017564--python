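"""Declarative genotype/subtype classification of cluster architectures.

A genome is assigned one of seven genotypes (G1-G7) by the presence and
absence of the eleven gamma-PGA-related genes (plus, for G3, an unusual
pgdS-ywtC spacing), then a subtype (SGx.y) by gene order, strand pattern
and spacing.  Rules are evaluated in listed order, first match wins; a
genome matching no genotype is "untyped", a genotype member matching no
subtype is "unassigned".

The packaged default table ("bacillus-g7-v1") encodes the published
seven-genotype scheme; orientations the scheme leaves unstated are either
wildcards (``*`` in a strand template) or distinct synthetic layouts so
that every subtype has a concrete, generatable template.
"""

from __future__ import annotations

import dataclasses
import importlib.resources

import yaml

from .architecture import ClusterArchitecture
from .errors import ConfigError

ALL_GENES = (
    "pghB",
    "pghC",
    "pghL",
    "pghZ",
    "ggt",
    "racE",
    "pgsB",
    "pgsC",
    "pgsA",
    "ywtC",
    "pgdS",
)


@dataclasses.dataclass(frozen=True)
class SpacingConstraint:
    """Unsigned gap between two genes must fall inside [min_bp, max_bp]."""

    a: str
    b: str
    min_bp: int
    max_bp: int


@dataclasses.dataclass
class GenotypeRule:
    label: str
    required: frozenset[str]
    forbidden: frozenset[str]
    order_template: tuple[str, ...] | None = None
    strand_template: str | None = None
    spacing_constraints: tuple[SpacingConstraint, ...] = ()
    parent: str | None = None
    #: generation hints: concrete strands for wildcard positions, gap overrides
    template_strands: str | None = None
    gap_overrides: dict[tuple[str, str], int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.required & self.forbidden:
            raise ConfigError(
                f"rule {self.label}: required and forbidden overlap: "
                f"{sorted(self.required & self.forbidden)}"
            )
        if self.order_template is not None and self.strand_template is not None:
            if len(self.order_template) != len(self.strand_template):
                raise ConfigError(
                    f"rule {self.label}: strand template length != order length"
                )
        if self.strand_template and set(self.strand_template) - set("+-*"):
            raise ConfigError(f"rule {self.label}: bad strand template")


@dataclasses.dataclass
class RuleSet:
    rules: list[GenotypeRule]
    version: str
    default: bool = False

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rules]
        if len(labels) != len(set(labels)):
            raise ConfigError("duplicate rule labels")
        by_label = {r.label: r for r in self.rules}
        for r in self.rules:
            if r.parent is not None:
                parent = by_label.get(r.parent)
                if parent is None:
                    raise ConfigError(f"rule {r.label}: unknown parent {r.parent}")
                if parent.parent is not None:
                    raise ConfigError(f"rule {r.label}: parent {r.parent} is itself a subtype")

    def genotypes(self) -> list[GenotypeRule]:
        return [r for r in self.rules if r.parent is None]

    def subtypes(self, genotype_label: str) -> list[GenotypeRule]:
        return [r for r in self.rules if r.parent == genotype_label]

    def __getitem__(self, label: str) -> GenotypeRule:
        for r in self.rules:
            if r.label == label:
                return r
        raise KeyError(label)


@dataclasses.dataclass
class GenotypeAssignment:
    genome_id: str
    genotype: str  # label or "untyped"
    subtype: str  # label or "unassigned"
    evidence: list[str]


def _parse_rule(doc: dict, parent: str | None, path: str) -> GenotypeRule:
    try:
        label = doc["label"]
    except KeyError:
        raise ConfigError(f"{path}: rule without a label") from None
    spacing = tuple(
        SpacingConstraint(s["a"], s["b"], int(s["min"]), int(s["max"]))
        for s in doc.get("spacing", [])
    )
    order = tuple(doc["order"]) if "order" in doc else None
    overrides = {}
    for key, val in (doc.get("gap_overrides") or {}).items():
        a, b = key.split("..")
        overrides[(a, b)] = int(val)
    return GenotypeRule(
        label=label,
        required=frozenset(doc.get("required", [])),
        forbidden=frozenset(doc.get("forbidden", [])),
        order_template=order,
        strand_template=doc.get("strands"),
        spacing_constraints=spacing,
        parent=parent,
        template_strands=doc.get("template_strands"),
        gap_overrides=overrides,
    )


def load_rules(path=None) -> RuleSet:
    """Load a rule table from YAML; ``None`` or ``"default"`` gives the
    packaged default scheme."""
    if path is None or path == "default":
        text = (
            importlib.resources.files("pgatype").joinpath("data/rules_default.yaml").read_text()
        )
        src = "<packaged default>"
    else:
        with open(path) as fh:
            text = fh.read()
        src = str(path)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{src}: invalid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "genotypes" not in doc:
        raise ConfigError(f"{src}: missing /genotypes")
    rules: list[GenotypeRule] = []
    for gdoc in doc["genotypes"]:
        grule = _parse_rule(gdoc, None, f"{src}#/genotypes")
        rules.append(grule)
        for sdoc in gdoc.get("subtypes", []) or []:
            srule = _parse_rule(sdoc, grule.label, f"{src}#/genotypes/{grule.label}/subtypes")
            if "required" not in sdoc:
                srule.required = grule.required
            if "forbidden" not in sdoc:
                srule.forbidden = grule.forbidden
            rules.append(srule)
    return RuleSet(rules=rules, version=str(doc.get("version", "unversioned")),
                   default=bool(doc.get("default", False)))


def serialize_rules(ruleset: RuleSet) -> str:
    """Canonical YAML form of a rule set (round-trips through load_rules)."""

    def rule_doc(r: GenotypeRule) -> dict:
        d: dict = {"label": r.label, "required": sorted(r.required),
                   "forbidden": sorted(r.forbidden)}
        if r.order_template is not None:
            d["order"] = list(r.order_template)
        if r.strand_template is not None:
            d["strands"] = r.strand_template
        if r.template_strands is not None:
            d["template_strands"] = r.template_strands
        if r.spacing_constraints:
            d["spacing"] = [
                {"a": s.a, "b": s.b, "min": s.min_bp, "max": s.max_bp}
                for s in r.spacing_constraints
            ]
        if r.gap_overrides:
            d["gap_overrides"] = {f"{a}..{b}": v for (a, b), v in r.gap_overrides.items()}
        return d

    doc = {"version": ruleset.version, "default": ruleset.default, "genotypes": []}
    for g in ruleset.genotypes():
        gd = rule_doc(g)
        subs = ruleset.subtypes(g.label)
        if subs:
            gd["subtypes"] = [rule_doc(s) for s in subs]
        doc["genotypes"].append(gd)
    return yaml.safe_dump(doc, sort_keys=False)


def _pair_gap(arch: ClusterArchitecture, a: str, b: str) -> int | None:
    from .architecture import intergenic_distance

    if a not in arch.present_set or b not in arch.present_set:
        return None
    return abs(intergenic_distance(arch, a, b))


def _check_rule(rule: GenotypeRule, arch: ClusterArchitecture, evidence: list[str]) -> bool:
    ok = True
    missing = rule.required - arch.present_set
    if missing:
        evidence.append(f"{rule.label}: missing required {sorted(missing)}")
        ok = False
    banned = rule.forbidden & arch.present_set
    if banned:
        evidence.append(f"{rule.label}: forbidden present {sorted(banned)}")
        ok = False
    if ok and rule.order_template is not None:
        observed = [g for g in arch.order if g in set(rule.order_template)]
        if tuple(observed) != rule.order_template:
            evidence.append(f"{rule.label}: order {observed} != template")
            ok = False
    if ok and rule.strand_template is not None and rule.order_template is not None:
        strands = {g[0]: g[3] for g in arch.genes}
        for gene, want in zip(rule.order_template, rule.strand_template):
            if want == "*":
                evidence.append(f"{rule.label}: strand[{gene}] wildcard")
                continue
            if strands.get(gene) != want:
                evidence.append(
                    f"{rule.label}: strand[{gene}]={strands.get(gene)} != {want}"
                )
                ok = False
                break
    if ok:
        for sc in rule.spacing_constraints:
            gap = _pair_gap(arch, sc.a, sc.b)
            if gap is None or not (sc.min_bp <= gap <= sc.max_bp):
                evidence.append(
                    f"{rule.label}: spacing {sc.a}-{sc.b}={gap} outside "
                    f"[{sc.min_bp}, {sc.max_bp}]"
                )
                ok = False
                break
    if ok:
        evidence.append(f"{rule.label}: all clauses satisfied")
    return ok


def assign_genotype(arch: ClusterArchitecture, rules: RuleSet) -> GenotypeAssignment:
    """First-match-wins classification of one architecture."""
    evidence: list[str] = []
    for grule in rules.genotypes():
        if not _check_rule(grule, arch, evidence):
            continue
        for srule in rules.subtypes(grule.label):
            if _check_rule(srule, arch, evidence):
                return GenotypeAssignment(arch.genome_id, grule.label, srule.label, evidence)
        return GenotypeAssignment(arch.genome_id, grule.label, "unassigned", evidence)
    return GenotypeAssignment(arch.genome_id, "untyped", "unassigned", evidence)


def summarize_genotypes(assignments: list[GenotypeAssignment]) -> dict[str, int]:
    """Exact counts per genotype and subtype; untyped counted separately."""
    counts: dict[str, int] = {}
    for a in assignments:
        if a.genotype == "untyped":
            counts["untyped"] = counts.get("untyped", 0) + 1
            continue
        counts[a.genotype] = counts.get(a.genotype, 0) + 1
        if a.subtype != "unassigned":
            counts[a.subtype] = counts.get(a.subtype, 0) + 1
    return counts
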
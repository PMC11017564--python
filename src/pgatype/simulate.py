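"""Ground-truth fixture generation.

Synthetic annotated genomes with planted gene-cluster architectures, and
protein panels with planted amino-acid substitutions.  Every generator is
a pure function of its spec and seed: outputs are byte-identical across
runs.  Protein composition and filler GC content are Bacillus-like but
cosmetic; gene lengths default to values close to the real enzymes
(pgsC smallest, ggt largest) and are configuration, not biology claims.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
import re

import numpy as np

from .align import GENE_ALIASES, PANEL_GENES, ReferencePanel
from .errors import PgatypeError, ValidationError
from .genomes import GeneFeature, GenomeRecord

#: approximate B. subtilis proteome residue frequencies (mole %)
_AA_FREQ = {
    "A": 7.7, "C": 0.8, "D": 5.2, "E": 7.2, "F": 4.5, "G": 6.9, "H": 2.3,
    "I": 7.3, "K": 7.1, "L": 9.7, "M": 2.8, "N": 4.0, "P": 3.7, "Q": 3.8,
    "R": 4.1, "S": 6.3, "T": 5.4, "V": 6.7, "W": 1.0, "Y": 3.5,
}
_AA_LETTERS = np.array(list(_AA_FREQ))
_AA_P = np.array(list(_AA_FREQ.values()))
_AA_P = _AA_P / _AA_P.sum()

#: one preferred B. subtilis codon per residue (deterministic back-translation)
_CODON = {
    "A": "GCA", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGC",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCG", "Q": "CAA", "R": "CGC", "S": "AGC", "T": "ACA", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"
_COMP = str.maketrans("ACGT", "TGCA")

#: default reference-protein lengths in residues
DEFAULT_LENGTHS = {
    "pgsB": 393, "pgsC": 149, "pgsA": 380, "ywtC": 120, "pgdS": 407,
    "racE": 272, "ggt": 587, "pghB": 219, "pghC": 225, "pghL": 215,
    "pghZ": 231,
}

#: filler GC fraction (Bacillus-like)
DEFAULT_GC = 0.43


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Random protein with Bacillus-like composition, starting with M."""
    body = rng.choice(_AA_LETTERS, size=length - 1, p=_AA_P)
    return "M" + "".join(body)


def generate_reference_panel(seed: int, lengths: dict[str, int] | None = None) -> ReferencePanel:
    """Deterministic random reference panel for the eleven genes."""
    lengths = dict(DEFAULT_LENGTHS if lengths is None else lengths)
    entries = {}
    for idx, gene in enumerate(sorted(lengths)):
        if lengths[gene] <= 0:
            raise ValidationError(f"panel gene {gene}: non-positive length")
        entries[gene] = random_protein(lengths[gene], _rng(seed, 101, idx))
    return ReferencePanel(entries, source_strain=f"synthetic-seed{seed}")


def back_translate(protein: str) -> str:
    """Most-frequent-codon back-translation with a TAA stop appended."""
    try:
        return "".join(_CODON[aa] for aa in protein) + _STOP
    except KeyError as exc:
        raise PgatypeError(f"cannot back-translate residue {exc}") from exc


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMP)[::-1]


def random_filler(length: int, rng: np.random.Generator, gc: float = DEFAULT_GC) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


@dataclasses.dataclass
class ArchitectureSpec:
    """Blueprint for one synthetic genome: which genes, where, how oriented."""

    genotype_label: str
    gene_order: list[str]
    strands: str
    spacings: list[int]  # n-1 adjacent end-to-start gaps, bp
    seed: int
    flank: int = 500
    n_decoys: int = 2
    subtype_label: str | None = None

    def __post_init__(self) -> None:
        n = len(self.gene_order)
        if len(self.strands) != n:
            raise ValidationError("strands length != gene count")
        if len(self.spacings) != max(n - 1, 0):
            raise ValidationError("need exactly n-1 spacings")
        if set(self.strands) - set("+-"):
            raise ValidationError(f"bad strand characters in {self.strands!r}")
        if len(set(self.gene_order)) != n:
            raise ValidationError("duplicate genes in order")


def generate_genome(
    spec: ArchitectureSpec,
    panel: ReferencePanel,
    variants: dict[str, str] | None = None,
) -> GenomeRecord:
    """Build an annotated genome realising ``spec``.

    Each planted gene is the back-translated panel protein (or the override
    in ``variants``); negative spacings overlap the later gene onto the
    earlier one.  Decoy CDS with random proteins are added in the flanks.
    """
    variants = variants or {}
    for gene in spec.gene_order:
        if gene not in panel:
            raise PgatypeError(f"spec gene {gene} missing from panel")
    rng = _rng(spec.seed, 202)
    proteins = {g: variants.get(g, panel[g]) for g in spec.gene_order}
    nts = {g: back_translate(p) for g, p in proteins.items()}

    coords: list[tuple[str, int, int]] = []
    pos = spec.flank
    for k, gene in enumerate(spec.gene_order):
        if k > 0:
            pos += spec.spacings[k - 1]
        if pos < 0:
            raise ValidationError(f"gene {gene} pushed before origin by overlaps")
        coords.append((gene, pos, pos + len(nts[gene])))
        pos = pos + len(nts[gene])
    total = (coords[-1][2] if coords else spec.flank) + spec.flank

    seq = np.frombuffer(random_filler(total, rng).encode(), dtype=np.uint8).copy()
    features: list[GeneFeature] = []
    for k, (gene, start, end) in enumerate(coords):
        strand = spec.strands[k]
        nt = nts[gene] if strand == "+" else reverse_complement(nts[gene])
        seq[start:end] = np.frombuffer(nt.encode(), dtype=np.uint8)
        features.append(
            GeneFeature(
                locus_tag=f"SYN_{k + 1:04d}",
                gene_name=gene,
                start=start,
                end=end,
                strand=strand,
                translation=proteins[gene],
                product=f"{gene} gene product",
            )
        )
    # decoy CDS in the flanks: random proteins unrelated to the panel
    decoy_len = 80
    decoy_nt_len = 3 * (decoy_len + 1)
    for d in range(spec.n_decoys):
        prot = random_protein(decoy_len, _rng(spec.seed, 303, d))
        nt = back_translate(prot)
        if d % 2 == 0:
            start = 40 + d * (decoy_nt_len + 20)
            if coords and start + decoy_nt_len > spec.flank:
                continue
        else:
            start = total - spec.flank + 60 + (d // 2) * (decoy_nt_len + 20)
            if start + decoy_nt_len > total - 10:
                continue
        seq[start : start + decoy_nt_len] = np.frombuffer(nt.encode(), dtype=np.uint8)
        features.append(
            GeneFeature(
                locus_tag=f"DEC_{d + 1:04d}",
                start=start,
                end=start + decoy_nt_len,
                strand="+",
                translation=prot,
                product="hypothetical protein",
            )
        )
    label = spec.subtype_label or spec.genotype_label
    return GenomeRecord(
        id=f"SYN{label.replace('.', '_')}s{spec.seed}",
        length=total,
        features=features,
        sequence=seq.tobytes().decode(),
        source_taxon="Bacillus sp. (synthetic)",
    )


# ---------------------------------------------------------------------------
# templates derived from the packaged rule table

_CLUSTER = ("pgsB", "pgsC", "pgsA", "ywtC", "pgdS")


def default_gap(a: str, b: str) -> int:
    """Default adjacent gap: tight inside the synthetase cluster, looser
    elsewhere; the ywtC-pgdS gap is the genotype-3 discriminator."""
    if a in _CLUSTER and b in _CLUSTER:
        return 100 if {a, b} == {"ywtC", "pgdS"} else 30
    return 200


def template_spec(label: str, ruleset=None, seed: int = 0) -> ArchitectureSpec:
    """ArchitectureSpec for a packaged genotype/subtype template label."""
    from .genotype import load_rules

    rules = ruleset if ruleset is not None else load_rules()
    rule = rules[label]
    if rule.order_template is None:
        raise PgatypeError(f"rule {label} has no order template to generate from")
    order = list(rule.order_template)
    strands = rule.template_strands or rule.strand_template.replace("*", "+")
    gaps = []
    for a, b in zip(order, order[1:]):
        gap = rule.gap_overrides.get((a, b), rule.gap_overrides.get((b, a)))
        gaps.append(gap if gap is not None else default_gap(a, b))
    genotype = rule.parent or rule.label
    return ArchitectureSpec(
        genotype_label=genotype,
        subtype_label=rule.label if rule.parent else None,
        gene_order=order,
        strands=strands,
        spacings=gaps,
        seed=seed,
    )


def generatable_labels(ruleset=None) -> list[str]:
    """All packaged rule labels that carry a concrete template (all
    subtypes, plus subtype-less genotypes like G4/G5)."""
    from .genotype import load_rules

    rules = ruleset if ruleset is not None else load_rules()
    out = []
    for g in rules.genotypes():
        subs = rules.subtypes(g.label)
        if subs:
            out.extend(s.label for s in subs)
        elif g.order_template is not None:
            out.append(g.label)
    return out


# ---------------------------------------------------------------------------
# planted-substitution strain panels

_NOTATION_RE = re.compile(r"^([A-Y])(\d+)([A-Y])$")


@dataclasses.dataclass
class MutationPlan:
    """Plant a fixed set of substitutions into a fraction of a panel."""

    protein: str
    events: list[str]  # "D74N"-style notations
    carrier_fraction: float
    n_strains: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValidationError("carrier_fraction outside [0, 1]")
        if self.n_strains < 1:
            raise ValidationError("n_strains must be >= 1")
        positions = [int(_NOTATION_RE.match(e).group(2)) for e in self.events
                     if _NOTATION_RE.match(e)]
        if len(positions) != len(self.events):
            bad = [e for e in self.events if not _NOTATION_RE.match(e)]
            raise ValidationError(f"malformed notations: {bad}")
        if len(set(positions)) != len(positions):
            raise ValidationError("two events at one position")


@dataclasses.dataclass
class StrainPanel:
    """Generated strain proteins plus the hidden carrier ground truth."""

    protein: str
    sequences: dict[str, str]
    carriers: set[str]
    reference: str


def apply_notations(reference: str, events: list[str]) -> str:
    seq = list(reference)
    for ev in events:
        m = _NOTATION_RE.match(ev)
        if not m:
            raise ValidationError(f"malformed notation {ev!r}")
        ref_aa, pos, alt_aa = m.group(1), int(m.group(2)), m.group(3)
        if pos < 1 or pos > len(reference):
            raise PgatypeError(f"event {ev}: position beyond reference length")
        if seq[pos - 1] != ref_aa:
            raise PgatypeError(
                f"event {ev}: reference has {seq[pos - 1]} at {pos}, not {ref_aa}"
            )
        seq[pos - 1] = alt_aa
    return "".join(seq)


def generate_strain_panel(plan: MutationPlan, panel: ReferencePanel) -> StrainPanel:
    """ceil(carrier_fraction * n) strains carry all planned events; the
    rest are exact reference copies.  Carrier assignment is a seeded
    permutation."""
    reference = panel[plan.protein]
    mutated = apply_notations(reference, plan.events)
    n_carriers = math.ceil(plan.carrier_fraction * plan.n_strains)
    rng = _rng(plan.seed, 404)
    order = rng.permutation(plan.n_strains)
    carrier_idx = set(order[:n_carriers].tolist())
    sequences = {}
    carriers = set()
    for i in range(plan.n_strains):
        name = f"S{i + 1:04d}"
        if i in carrier_idx:
            sequences[name] = mutated
            carriers.add(name)
        else:
            sequences[name] = reference
    return StrainPanel(plan.protein, sequences, carriers, reference)


# ---------------------------------------------------------------------------
# dataset emission (GenBank files + ground-truth manifest)

def generate_dataset(labels: list[str], out_dir, seed: int, panel: ReferencePanel | None = None):
    """Write one GenBank genome per template label plus manifest.json."""
    from .genomes import write_genbank

    os.makedirs(out_dir, exist_ok=True)
    panel = panel or generate_reference_panel(seed)
    manifest = {"seed": int(seed), "genomes": []}
    for k, label in enumerate(labels):
        spec = template_spec(label, seed=seed + k)
        record = generate_genome(spec, panel)
        fname = f"{record.id}.gbk"
        write_genbank(record, os.path.join(out_dir, fname))
        manifest["genomes"].append(
            {
                "file": fname,
                "genome_id": record.id,
                "genotype": spec.genotype_label,
                "subtype": spec.subtype_label,
                "genes": [
                    {"gene": g, "start": s, "end": e, "strand": st}
                    for g, s, e, st in (
                        (f.gene_name, f.start, f.end, f.strand)
                        for f in record.features
                        if f.gene_name
                    )
                ],
            }
        )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
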
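"""Cluster architecture: gene order, strands and intergenic spacing.

The spacing convention is the end-to-start gap between two genes ordered
by genome position (negative when they overlap).  A start-to-start
alternative is available for sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
import json

from .align import GeneHit
from .errors import PgatypeError, ValidationError
from .genomes import GenomeRecord


@dataclasses.dataclass
class ClusterArchitecture:
    """Ordered layout of the detected gamma-PGA genes along one genome."""

    genome_id: str
    genes: list[tuple[str, int, int, str, int]]  # (name, start, end, strand, length)
    present_set: set[str]
    strand_pattern: str
    spacings: dict[tuple[str, str], int]

    @property
    def order(self) -> list[str]:
        return [g[0] for g in self.genes]

    def to_json(self) -> str:
        doc = {
            "genome_id": self.genome_id,
            "genes": [
                {"gene": n, "start": s, "end": e, "strand": st, "length": ln}
                for n, s, e, st, ln in self.genes
            ],
            "strand_pattern": self.strand_pattern,
            "spacings": {f"{a}..{b}": d for (a, b), d in self.spacings.items()},
        }
        return json.dumps(doc, indent=2, sort_keys=True)


#: pair whose spacing discriminates genotype 3 architectures
DIAGNOSTIC_PAIR = ("pgdS", "ywtC")


def build_architecture(hits: list[GeneHit], record: GenomeRecord) -> ClusterArchitecture:
    """Summarise gene hits into a :class:`ClusterArchitecture`.

    Spacings are recorded for every adjacent pair and, when both members
    are present, for the diagnostic (pgdS, ywtC) pair.
    """
    names = [h.gene_name for h in hits]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate gene hits for {dupes}")
    ordered = sorted(hits, key=lambda h: h.feature.start)
    genes = [
        (h.gene_name, h.feature.start, h.feature.end, h.feature.strand, h.feature.length)
        for h in ordered
    ]
    arch = ClusterArchitecture(
        genome_id=record.id,
        genes=genes,
        present_set={g[0] for g in genes},
        strand_pattern="".join(g[3] for g in genes),
        spacings={},
    )
    for prev, nxt in zip(genes, genes[1:]):
        arch.spacings[(prev[0], nxt[0])] = nxt[1] - prev[2]
    a, b = DIAGNOSTIC_PAIR
    if a in arch.present_set and b in arch.present_set and (a, b) not in arch.spacings and (
        b,
        a,
    ) not in arch.spacings:
        arch.spacings[(a, b)] = intergenic_distance(arch, a, b)
    return arch


def intergenic_distance(
    arch: ClusterArchitecture, a: str, b: str, convention: str = "gap"
) -> int:
    """Signed bp distance between two named genes.

    ``gap`` (default): downstream start minus upstream end — negative when
    the genes overlap.  ``start`` : distance between start coordinates.
    """
    lookup = {g[0]: g for g in arch.genes}
    for name in (a, b):
        if name not in lookup:
            raise PgatypeError(f"gene {name} not present in architecture {arch.genome_id}")
    ga, gb = lookup[a], lookup[b]
    up, down = (ga, gb) if ga[1] <= gb[1] else (gb, ga)
    if convention == "gap":
        return down[1] - up[2]
    if convention == "start":
        return down[1] - up[1]
    raise PgatypeError(f"unknown distance convention {convention!r}")


def architecture_svg(arch: ClusterArchitecture, width: int = 900) -> str:
    """Render one genome row as an SVG arrow diagram (scaled bp axis)."""
    if not arch.genes:
        return '<svg xmlns="http://www.w3.org/2000/svg" width="10" height="10"/>'
    lo = min(g[1] for g in arch.genes)
    hi = max(g[2] for g in arch.genes)
    span = max(hi - lo, 1)
    scale = (width - 40) / span
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="80">',
        f'<line x1="20" y1="40" x2="{width - 20}" y2="40" stroke="black"/>',
    ]
    for name, s, e, strand, _len in arch.genes:
        x0 = 20 + (s - lo) * scale
        x1 = 20 + (e - lo) * scale
        head = min(8.0, x1 - x0)
        if strand == "+":
            pts = f"{x0},30 {x1 - head},30 {x1},40 {x1 - head},50 {x0},50"
        else:
            pts = f"{x1},30 {x0 + head},30 {x0},40 {x0 + head},50 {x1},50"
        parts.append(f'<polygon points="{pts}" fill="#7fa8d9" stroke="black"/>')
        parts.append(
            f'<text x="{(x0 + x1) / 2:.1f}" y="25" font-size="10" '
            f'text-anchor="middle">{name}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts)
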
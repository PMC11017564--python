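"""Convenience wrappers chaining detection, architecture and genotyping."""

from __future__ import annotations

from .align import DEFAULT_SCHEME, ReferencePanel, ScoringScheme, find_gene_hits
from .architecture import ClusterArchitecture, build_architecture
from .genomes import GenomeRecord
from .genotype import GenotypeAssignment, RuleSet, assign_genotype, load_rules


def scan_genome(
    record: GenomeRecord,
    panel: ReferencePanel,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_identity: float = 0.30,
    min_coverage: float = 0.50,
) -> ClusterArchitecture:
    """Detect panel genes in one genome and summarise their architecture."""
    hits = find_gene_hits(record, panel, scheme, min_identity, min_coverage)
    return build_architecture(hits, record)


def classify_genome(
    record: GenomeRecord,
    panel: ReferencePanel,
    rules: RuleSet | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_identity: float = 0.30,
    min_coverage: float = 0.50,
) -> GenotypeAssignment:
    """Full detect -> architecture -> genotype chain for one genome."""
    rules = rules if rules is not None else load_rules()
    arch = scan_genome(record, panel, scheme, min_identity, min_coverage)
    return assign_genotype(arch, rules)
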
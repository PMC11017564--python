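"""Reference-anchored substitution catalogs and identity ranges.

Substitutions are reported in the conventional "D74N" notation: reference
residue, 1-based position on the reference, variant residue.  Positions
are anchored on the reference sequence — alignment columns where the
reference carries a gap (insertions in the query) shift no positions —
which is what makes notations aggregatable across strains.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .align import DEFAULT_SCHEME, ScoringScheme, align_pair
from .errors import PgatypeError, ValidationError


@dataclasses.dataclass(frozen=True)
class SubstitutionEvent:
    position: int  # 1-based on the reference
    ref_aa: str
    alt_aa: str
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValidationError("substitution with identical residues")
        if self.position < 1:
            raise ValidationError("positions are 1-based")

    @property
    def notation(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclasses.dataclass(frozen=True)
class IndelEvent:
    """kind "ins": ``seq`` inserted after reference position ``position``
    (0 = before the first residue); kind "del": ``length`` reference
    residues deleted starting at 1-based ``position``."""

    kind: str
    position: int
    seq: str = ""
    length: int = 0


def call_variants(
    reference: str,
    query: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    protein: str | None = None,
) -> tuple[list[SubstitutionEvent], list[IndelEvent]]:
    """Globally align query to reference and catalog every difference."""
    if "-" in reference:
        raise PgatypeError("reference must be ungapped")
    if reference == query:
        return [], []
    res = align_pair(reference, query, scheme)
    subs: list[SubstitutionEvent] = []
    indels: list[IndelEvent] = []
    ref_pos = 0
    pending_ins: list[str] = []
    pending_del = 0
    del_start = 0
    for x, y in zip(res.aligned_a, res.aligned_b):
        if x != "-" and pending_ins:
            indels.append(IndelEvent("ins", ref_pos, seq="".join(pending_ins)))
            pending_ins = []
        if (x == "-" or y != "-") and pending_del:
            indels.append(IndelEvent("del", del_start, length=pending_del))
            pending_del = 0
        if x != "-" and y != "-":
            ref_pos += 1
            if x != y:
                subs.append(SubstitutionEvent(ref_pos, x, y, protein))
        elif x == "-":
            pending_ins.append(y)
        else:  # y == "-": deletion of reference residue
            ref_pos += 1
            if pending_del == 0:
                del_start = ref_pos
            pending_del += 1
    if pending_ins:
        indels.append(IndelEvent("ins", ref_pos, seq="".join(pending_ins)))
    if pending_del:
        indels.append(IndelEvent("del", del_start, length=pending_del))
    return subs, indels


def call_substitutions(
    reference: str,
    query: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    protein: str | None = None,
) -> list[SubstitutionEvent]:
    """Substitutions only (indels catalogued separately by call_variants)."""
    return call_variants(reference, query, scheme, protein)[0]


def apply_variants(
    reference: str, subs: list[SubstitutionEvent], indels: list[IndelEvent]
) -> str:
    """Reconstruct the query from the reference and its called events."""
    deleted = set()
    insert_after: dict[int, str] = {}
    for ind in indels:
        if ind.kind == "del":
            deleted.update(range(ind.position, ind.position + ind.length))
        else:
            insert_after[ind.position] = insert_after.get(ind.position, "") + ind.seq
    replaced = {s.position: s.alt_aa for s in subs}
    out = [insert_after.get(0, "")]
    for pos in range(1, len(reference) + 1):
        if pos not in deleted:
            out.append(replaced.get(pos, reference[pos - 1]))
        out.append(insert_after.get(pos, ""))
    return "".join(out)


@dataclasses.dataclass
class MutationFrequencyTable:
    protein: str
    panel_size: int
    rows: list[tuple[str, int, float]]  # (notation, count, frequency)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=["notation", "count", "frequency"])
        df["percent"] = (df["frequency"] * 100).map(lambda v: f"{v:.2f}")
        return df

    def to_tsv(self) -> str:
        return self.to_dataframe().to_csv(sep="\t", index=False)


def _notation_position(notation: str) -> int:
    return int(notation[1:-1])


def substitution_frequencies(
    per_strain_events: dict[str, list[SubstitutionEvent]], panel_size: int
) -> MutationFrequencyTable:
    """Count strains carrying each identical notation; frequency = count /
    panel_size.  Rows sorted by descending frequency then position."""
    if panel_size < 1:
        raise ValidationError("panel_size must be >= 1")
    proteins = {e.protein for evs in per_strain_events.values() for e in evs}
    proteins.discard(None)
    if len(proteins) > 1:
        raise ValidationError(f"events from multiple proteins: {sorted(proteins)}")
    protein = proteins.pop() if proteins else "unknown"
    counts: dict[str, int] = {}
    for events in per_strain_events.values():
        for notation in {e.notation for e in events}:
            counts[notation] = counts.get(notation, 0) + 1
    rows = [(n, c, c / panel_size) for n, c in counts.items()]
    rows.sort(key=lambda r: (-r[2], _notation_position(r[0])))
    return MutationFrequencyTable(protein, panel_size, rows)


def catalog_panel(
    reference: str,
    sequences: dict[str, str],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    protein: str | None = None,
) -> dict[str, list[SubstitutionEvent]]:
    """Per-strain substitution calls against one reference.

    Identical strain sequences share one alignment (memoised), so large
    panels of few haplotypes stay cheap.
    """
    cache: dict[str, list[SubstitutionEvent]] = {}
    out = {}
    for strain, seq in sequences.items():
        if seq not in cache:
            cache[seq] = call_substitutions(reference, seq, scheme, protein)
        out[strain] = cache[seq]
    return out


def identity_matrix(
    panel: dict[str, str], scheme: ScoringScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Symmetric strain-by-strain identity table (unit diagonal)."""
    labels = list(panel)
    if len(labels) < 2:
        raise PgatypeError("identity_matrix needs at least 2 strains")
    df = pd.DataFrame(1.0, index=labels, columns=labels)
    cache: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            key = (panel[a], panel[b])
            if key not in cache:
                cache[key] = (
                    1.0 if key[0] == key[1] else align_pair(key[0], key[1], scheme).identity
                )
            df.loc[a, b] = df.loc[b, a] = cache[key]
    return df


def identity_range(matrix: pd.DataFrame) -> tuple[float, float]:
    """(min, max) of the off-diagonal identities."""
    vals = [
        matrix.iloc[i, j]
        for i in range(len(matrix))
        for j in range(len(matrix))
        if i != j
    ]
    return min(vals), max(vals)
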
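"""Pairwise protein alignment and homology-based gene detection.

The aligner is a three-state (Gotoh) affine-gap dynamic program.  A gap of
length L costs ``gap_open + (L - 1) * gap_extend``; a direction switch
between an up-gap and a left-gap opens a new gap.  Traceback is fully
deterministic with the tie-break order diagonal > up > left (and state
preference match > up-gap > left-gap), so alignments are bit-stable.

Identity is defined as identical columns divided by total alignment
columns, i.e. gap columns count in the denominator but never the
numerator.  An alternative "ungapped-columns" denominator is available via
``identity_mode``.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np
from Bio.Align import substitution_matrices

from .errors import PgatypeError, ValidationError
from .genomes import GeneFeature, GenomeRecord

PANEL_GENES = (
    "pgsB",
    "pgsC",
    "pgsA",
    "ywtC",
    "pgdS",
    "racE",
    "ggt",
    "pghB",
    "pghC",
    "pghL",
    "pghZ",
)

#: the cluster's small fourth ORF is labelled both ywtC and pgsE in the
#: literature; both names resolve to one panel slot.
GENE_ALIASES = {"pgsE": "ywtC"}

_AA = "ACDEFGHIKLMNPQRSTVWYX"
_NEG = -1e12  # acts as -inf but stays finite under addition


def canonical_gene_name(name: str) -> str:
    return GENE_ALIASES.get(name, name)


@functools.lru_cache(maxsize=4)
def _load_matrix(name: str) -> np.ndarray:
    """26x26 integer score matrix indexed by ``ord(ch) - ord('A')``.

    X scores 0 against everything (unknown residue is alignment-neutral).
    """
    m = substitution_matrices.load(name)
    out = np.zeros((26, 26), dtype=np.int64)
    for a in m.alphabet:
        for b in m.alphabet:
            if a.isalpha() and b.isalpha():
                out[ord(a) - 65, ord(b) - 65] = int(m[a, b])
    xi = ord("X") - 65
    out[xi, :] = 0
    out[:, xi] = 0
    return out


@dataclasses.dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties."""

    matrix: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1
    mode: str = "global"  # or "local"

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValidationError(
                f"require gap_open <= gap_extend < 0, got {self.gap_open}/{self.gap_extend}"
            )
        if self.mode not in ("global", "local"):
            raise ValidationError(f"unknown alignment mode {self.mode!r}")

    def score_matrix(self) -> np.ndarray:
        return _load_matrix(self.matrix)

    def pair_score(self, a: str, b: str) -> int:
        return int(self.score_matrix()[ord(a) - 65, ord(b) - 65])


DEFAULT_SCHEME = ScoringScheme()


@dataclasses.dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: int
    identity: float
    coverage_a: float
    coverage_b: float

    @property
    def columns(self) -> int:
        return len(self.aligned_a)


def _encode(seq: str, which: str) -> np.ndarray:
    if not seq:
        raise PgatypeError(f"sequence {which} is empty")
    for i, ch in enumerate(seq):
        if ch not in _AA:
            raise PgatypeError(
                f"sequence {which}: illegal character {ch!r} at position {i + 1}"
            )
    return np.frombuffer(seq.encode(), dtype=np.uint8).astype(np.int64) - 65


def _fill_global(S: np.ndarray, go: float, ge: float):
    """Fill the three Gotoh matrices for a global alignment.

    ``S`` is the (n, m) column-vs-column substitution score matrix, so the
    same recurrence serves residue-residue and profile-profile alignment.
    M: i aligned to j; X: gap in b (consumes a, "up"); Y: gap in a
    (consumes b, "left").  Y has an in-row dependency solved with a running
    cummax over (source + go - k*ge).
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    Y[0, 1:] = go + (j - 1) * ge
    i = np.arange(1, n + 1)
    X[1:, 0] = go + (i - 1) * ge
    ks = np.arange(0, m)  # source columns for Y
    for r in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[r - 1, :-1], X[r - 1, :-1]), Y[r - 1, :-1])
        M[r, 1:] = best_prev + S[r - 1]
        X[r, 1:] = np.maximum(
            np.maximum(M[r - 1, 1:], Y[r - 1, 1:]) + go, X[r - 1, 1:] + ge
        )
        # column 0 of X already set; M/Y stay -inf there
        src = np.maximum(M[r, :-1], X[r, :-1])  # open a left-gap after col k
        Y[r, 1:] = np.maximum.accumulate(src + go - ks * ge) + ks * ge
    return M, X, Y


def _traceback_ops(M, X, Y, go, ge):
    """Deterministic global traceback to a list of ops, left to right.

    Ops are ``"M"`` (consume one of each), ``"X"`` (consume row item, gap in
    b) and ``"Y"`` (gap in a).  Tie-break: diagonal > up > left.
    """
    n, m = M.shape[0] - 1, M.shape[1] - 1
    # state preference everywhere: M (diagonal) > X (up) > Y (left)
    # integer-valued scores in float64: plain comparisons are exact
    vals = (M[n, m], X[n, m], Y[n, m])
    state = 0 if vals[0] >= vals[1] and vals[0] >= vals[2] else (1 if vals[1] >= vals[2] else 2)
    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:  # match/mismatch column
            ops.append("M")
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
            state = 0 if prev[0] >= prev[1] and prev[0] >= prev[2] else (
                1 if prev[1] >= prev[2] else 2
            )
        elif state == 1:  # up: gap in b
            ops.append("X")
            val = X[i, j]
            i -= 1
            if abs(M[i, j] + go - val) < 0.5:
                state = 0
            elif abs(X[i, j] + ge - val) < 0.5:
                state = 1
            else:
                state = 2
        else:  # left: gap in a
            ops.append("Y")
            val = Y[i, j]
            j -= 1
            if abs(M[i, j] + go - val) < 0.5:
                state = 0
            elif abs(X[i, j] + go - val) < 0.5:
                state = 1
            else:
                state = 2
    ops.reverse()
    return ops


def _fill_local(ea, eb, mat, go, ge):
    n, m = len(ea), len(eb)
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    ks = np.arange(0, m)
    for r in range(1, n + 1):
        sub = mat[ea[r - 1], eb]
        best_prev = np.maximum(np.maximum(M[r - 1, :-1], X[r - 1, :-1]), Y[r - 1, :-1])
        M[r, 1:] = np.maximum(best_prev + sub, 0.0)
        X[r, 1:] = np.maximum(
            np.maximum(M[r - 1, 1:], Y[r - 1, 1:]) + go, X[r - 1, 1:] + ge
        )
        src = np.maximum(M[r, :-1], X[r, :-1])
        Y[r, 1:] = np.maximum.accumulate(src + go - ks * ge) + ks * ge
    return M, X, Y


def align_pair(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> AlignmentResult:
    """Optimal pairwise alignment of two protein sequences.

    Global mode aligns end to end (terminal gaps penalised); local mode is
    Smith-Waterman over the same affine gap model.
    """
    ea, eb = _encode(a, "a"), _encode(b, "b")
    mat = scheme.score_matrix()
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    if scheme.mode == "global":
        S = mat[ea][:, eb].astype(float)
        M, X, Y = _fill_global(S, go, ge)
        n, m = len(a), len(b)
        score = int(round(max(M[n, m], X[n, m], Y[n, m])))
        ops = _traceback_ops(M, X, Y, go, ge)
        ia = ib = 0
        ca: list[str] = []
        cb: list[str] = []
        for op in ops:
            if op == "M":
                ca.append(a[ia]); cb.append(b[ib]); ia += 1; ib += 1
            elif op == "X":
                ca.append(a[ia]); cb.append("-"); ia += 1
            else:
                ca.append("-"); cb.append(b[ib]); ib += 1
        aa, ab = "".join(ca), "".join(cb)
        cov_a = cov_b = 1.0
    else:
        M, X, Y = _fill_local(ea, eb, mat, go, ge)
        flat = int(np.argmax(M))
        i, j = divmod(flat, M.shape[1])
        score = int(round(M[i, j]))
        if score == 0:
            return AlignmentResult("", "", 0, 0.0, 0.0, 0.0)
        end_i, end_j = i, j
        out_a: list[str] = []
        out_b: list[str] = []
        state = 0
        while (i > 0 or j > 0) and not (state == 0 and M[i, j] == 0.0):
            if state == 0:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                sub = mat[ea[i - 1], eb[j - 1]]
                prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
                if abs(prev[0] + sub - M[i, j]) < 0.5:
                    state = 0
                elif abs(prev[1] + sub - M[i, j]) < 0.5:
                    state = 1
                else:
                    state = 2
                i, j = i - 1, j - 1
            elif state == 1:
                out_a.append(a[i - 1])
                out_b.append("-")
                val = X[i, j]
                i -= 1
                if abs(M[i, j] + go - val) < 0.5:
                    state = 0
                elif abs(X[i, j] + ge - val) < 0.5:
                    state = 1
                else:
                    state = 2
            else:
                out_a.append("-")
                out_b.append(b[j - 1])
                val = Y[i, j]
                j -= 1
                if abs(M[i, j] + go - val) < 0.5:
                    state = 0
                elif abs(X[i, j] + go - val) < 0.5:
                    state = 1
                else:
                    state = 2
        aa, ab = "".join(reversed(out_a)), "".join(reversed(out_b))
        cov_a = (end_i - i) / len(a)
        cov_b = (end_j - j) / len(b)
    ident = alignment_identity(aa, ab)
    return AlignmentResult(aa, ab, score, ident, cov_a, cov_b)


def alignment_identity(aligned_a: str, aligned_b: str, identity_mode: str = "all_columns") -> float:
    """Fraction of identical columns.

    ``all_columns`` (default) divides by the full alignment length,
    ``ungapped_columns`` by columns where neither row has a gap.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValidationError("aligned rows differ in length")
    same = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    if identity_mode == "all_columns":
        denom = len(aligned_a)
    elif identity_mode == "ungapped_columns":
        denom = sum(1 for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-")
    else:
        raise ValidationError(f"unknown identity mode {identity_mode!r}")
    return same / denom if denom else 0.0


@dataclasses.dataclass
class ReferencePanel:
    """Reference proteins for the eleven gamma-PGA-related genes."""

    entries: dict[str, str]
    source_strain: str = "synthetic"

    def __post_init__(self) -> None:
        canon: dict[str, str] = {}
        for name, seq in self.entries.items():
            cname = canonical_gene_name(name)
            if cname in canon and canon[cname] != seq:
                raise ValidationError(f"panel gene {cname} given twice with different sequences")
            if not seq:
                raise ValidationError(f"panel gene {cname}: empty sequence")
            canon[cname] = seq
        self.entries = canon

    def __getitem__(self, gene: str) -> str:
        return self.entries[canonical_gene_name(gene)]

    def __contains__(self, gene: str) -> bool:
        return canonical_gene_name(gene) in self.entries

    def genes(self) -> list[str]:
        return list(self.entries)


def read_panel_fasta(path) -> ReferencePanel:
    """Load a reference panel from multi-FASTA, headers ``gene|source_strain``."""
    entries: dict[str, str] = {}
    strain = "unknown"
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    entries[name] = "".join(chunks)
                fields = line[1:].split("|")
                name = fields[0].strip()
                if len(fields) > 1:
                    strain = fields[1].strip()
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        entries[name] = "".join(chunks)
    return ReferencePanel(entries, source_strain=strain)


def write_panel_fasta(panel: ReferencePanel, path) -> None:
    with open(path, "w") as fh:
        for gene, seq in panel.entries.items():
            fh.write(f">{gene}|{panel.source_strain}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


@dataclasses.dataclass(frozen=True)
class GeneHit:
    gene_name: str
    feature: GeneFeature
    identity: float
    coverage: float
    score: int


def _self_score(seq: str, scheme: ScoringScheme) -> int:
    mat = scheme.score_matrix()
    e = _encode(seq, "seq")
    return int(mat[e, e].sum())


def find_gene_hits(
    record: GenomeRecord,
    panel: ReferencePanel,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_identity: float = 0.30,
    min_coverage: float = 0.50,
) -> list[GeneHit]:
    """Locate each panel gene in a genome by protein alignment.

    For every panel gene the best-scoring CDS passing both thresholds is
    reported; each CDS can serve at most one gene (assigned greedily by
    descending score, ties broken by genome order).  Coverage is the
    fraction of the reference covered by residue-residue columns.
    Candidates shorter than ``min_coverage`` times the reference length are
    skipped without alignment.
    """
    candidates: list[tuple[str, GeneFeature, float, float, int]] = []
    for gene, ref in panel.entries.items():
        for feat in record.features:
            q = feat.translation
            if not q:
                continue
            if len(q) < min_coverage * len(ref) or len(q) > len(ref) / max(min_coverage, 1e-9):
                continue
            if q == ref:  # exact copy short-circuit
                ident, cov, score = 1.0, 1.0, _self_score(ref, scheme)
            else:
                res = align_pair(ref, q, scheme)
                both = sum(
                    1 for x, y in zip(res.aligned_a, res.aligned_b) if x != "-" and y != "-"
                )
                ident, cov, score = res.identity, both / len(ref), res.score
            if ident >= min_identity and cov >= min_coverage:
                candidates.append((gene, feat, ident, cov, score))
    candidates.sort(key=lambda c: (-c[4], c[1].start))
    hits: list[GeneHit] = []
    used_genes: set[str] = set()
    used_loci: set[str] = set()
    for gene, feat, ident, cov, score in candidates:
        if gene in used_genes or feat.locus_tag in used_loci:
            continue
        used_genes.add(gene)
        used_loci.add(feat.locus_tag)
        hits.append(GeneHit(gene, feat, ident, cov, score))
    hits.sort(key=lambda h: h.feature.start)
    return hits


def percent_identity_range(results) -> tuple[float, float]:
    """Exact (min, max) of alignment identities over a non-empty collection."""
    idents = [r.identity if isinstance(r, AlignmentResult) else float(r) for r in results]
    if not idents:
        raise PgatypeError("percent_identity_range: empty input")
    return min(idents), max(idents)
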
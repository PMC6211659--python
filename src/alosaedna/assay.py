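"""In-silico screening of a qPCR primer/probe set against a CO1 reference panel.

The river herring assay amplifies a short (164 bp) region of mitochondrial
CO1 shared by alewife (*Alosa pseudoharengus*) and blueback herring
(*A. aestivalis*), with a molecular-beacon probe providing specificity
against closely related alosids (hickory and American shad).  This module
answers the questions asked of such an assay before it is trusted in the
field: where does each primer land on a candidate template, how long is the
amplicon, how many mismatches does each oligo carry against each species,
and which amplicon positions are fixed differences (diagnostic SNPs)
between the two target species.

Primer matching is Hamming distance on equal-length windows — primers are
short and the specificity argument is mismatch-count based, so indel
alignment would add nothing.  IUPAC ambiguity codes in a reference count as
a match when the primer base is a member of the code's set.  Coordinates
are 1-based inclusive throughout, so "amplicon bp 104" means the 104th base
of the amplicon counting the first base of the forward-primer footprint
as 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "IUPAC_SETS",
    "ReferenceSet",
    "AssayOligos",
    "AmpliconHit",
    "DiagnosticSite",
    "RIVER_HERRING_OLIGOS",
    "read_reference_fasta",
    "hamming_mismatches",
    "find_amplicon",
    "probe_mismatch_table",
    "find_diagnostic_snps",
]

IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

GAP_CHARS = "-."


@dataclass(frozen=True)
class AssayOligos:
    """Primer pair plus probe, all written 5'→3' as synthesized.

    The reverse primer is the reverse complement of the template sense
    strand, as is conventional.  ``stem`` gives the lengths of the beacon's
    self-complementary 5' and 3' arms; only the loop between them binds the
    target and only the loop is compared against templates.
    """

    forward: str
    reverse: str
    probe: str
    stem: tuple[int, int] = (6, 6)

    def __post_init__(self) -> None:
        for name in ("forward", "reverse", "probe"):
            seq = getattr(self, name)
            if len(seq) < 10:
                raise ValueError(f"{name} oligo shorter than 10 nt: {seq!r}")
            if not set(seq) <= set("ACGT"):
                raise ValueError(f"{name} oligo must be uppercase ACGT: {seq!r}")

    @property
    def probe_loop(self) -> str:
        """Target-binding region of the beacon (stem arms stripped)."""
        lo, hi = self.stem
        return self.probe[lo: len(self.probe) - hi]


#: The published river herring CO1 assay (forward/reverse primers and the
#: FAM/IOWABlack molecular beacon).  The CGCGAT…ATCGCG hairpin arms of the
#: beacon hybridize to each other, not the target, so they are excluded
#: from mismatch counting via ``stem=(6, 6)``.
RIVER_HERRING_OLIGOS = AssayOligos(
    forward="ATGAGCTTCTGACTACTT",
    reverse="GATAGTTAGATCGACGGA",
    probe="CGCGATCGGATGAACAGTCTACCCGCCCTTGATCGCG",
)


@dataclass
class ReferenceSet:
    """Species-labelled nucleotide references, optionally column-aligned."""

    records: list[tuple[str, str]]
    aligned: bool = False

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.records]
        if len(labels) != len(set(labels)):
            raise ValueError("reference labels must be unique")
        allowed = set(IUPAC_SETS) | set(GAP_CHARS)
        for lab, seq in self.records:
            if not seq:
                raise ValueError(f"empty sequence for {lab!r}")
            bad = set(seq.upper()) - allowed
            if bad:
                raise ValueError(f"non-IUPAC characters {bad} in {lab!r}")
        if self.aligned:
            lengths = {len(seq) for _, seq in self.records}
            if len(lengths) > 1:
                raise ValueError("aligned=True but sequence lengths differ")

    def species_of(self, label: str) -> str:
        """Species part of a record label (text before the first '|')."""
        return label.split("|", 1)[0]

    def by_species(self, species: str) -> list[tuple[str, str]]:
        return [(lab, seq) for lab, seq in self.records
                if self.species_of(lab) == species]

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab, _ in self.records:
            seen.setdefault(self.species_of(lab))
        return list(seen)


def read_reference_fasta(path, aligned: bool | None = None) -> ReferenceSet:
    """Read a FASTA reference panel.

    Record ids are kept verbatim; the species is taken as the id up to the
    first ``|`` (``Alosa_pseudoharengus|acc123``).  If ``aligned`` is None
    it is inferred: all sequences equal length and at least one gap, or
    simply all equal length.
    """
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if aligned is None:
        lengths = {len(s) for _, s in records}
        aligned = len(lengths) == 1
    return ReferenceSet(records=records, aligned=aligned)


@dataclass
class AmpliconHit:
    """A qualifying primer-pair placement on a template sense strand.

    ``start``/``end`` are 1-based inclusive on the (gap-stripped) input
    sequence and bracket both primer footprints.  ``strand`` is +1 when the
    forward primer lands on the given strand, -1 when the amplicon was
    found on the reverse complement (coordinates still refer to the input).
    """

    species: str
    start: int
    end: int
    length: int
    fwd_mismatches: int
    rev_mismatches: int
    probe_mismatches: int | None = None
    strand: int = 1
    ambiguous: bool = False
    alternatives: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length != self.end - self.start + 1:
            raise ValueError("length must equal end - start + 1")
        if min(self.fwd_mismatches, self.rev_mismatches) < 0:
            raise ValueError("mismatch counts must be >= 0")


def hamming_mismatches(oligo: str, window: str) -> int:
    """Mismatches of an ACGT oligo against an equal-length IUPAC window."""
    if len(oligo) != len(window):
        raise ValueError("oligo and window must be equal length")
    mm = 0
    for a, b in zip(oligo, window.upper()):
        allowed = IUPAC_SETS.get(b)
        if allowed is None or a not in allowed:
            mm += 1
    return mm


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _scan(template: str, oligo: str, max_mm: int) -> list[tuple[int, int]]:
    """All 0-based start offsets where oligo binds with <= max_mm mismatches."""
    n, k = len(template), len(oligo)
    out = []
    for i in range(n - k + 1):
        mm = hamming_mismatches(oligo, template[i: i + k])
        if mm <= max_mm:
            out.append((i, mm))
    return out


def strip_gaps(seq: str) -> str:
    for g in GAP_CHARS:
        seq = seq.replace(g, "")
    return seq


def _best_pair(template: str, oligos: AssayOligos, max_mm: int, max_len: int):
    """Minimal-total-mismatch (fwd, rev) placement on one strand.

    Returns (start0, end0, fwd_mm, rev_mm, ambiguous, alternatives) with
    0-based inclusive coordinates, or None.
    """
    fwd_sites = _scan(template, oligos.forward, max_mm)
    rev_sites = _scan(template, _revcomp(oligos.reverse), max_mm)
    if not fwd_sites or not rev_sites:
        return None
    best = None
    placements: list[tuple[int, int, int, int]] = []
    for fi, fmm in fwd_sites:
        for ri, rmm in rev_sites:
            end = ri + len(oligos.reverse) - 1
            length = end - fi + 1
            if ri <= fi + len(oligos.forward) - 1 or length > max_len:
                continue
            placements.append((fmm + rmm, fi, end, rmm))
    if not placements:
        return None
    placements.sort()
    total, fi, end, rmm = placements[0]
    ties = [(p[1], p[2]) for p in placements if p[0] == total]
    ambiguous = len(ties) > 1
    return fi, end, total - rmm, rmm, ambiguous, ties[1:]


def find_amplicon(
    label: str,
    sequence: str,
    oligos: AssayOligos,
    max_mm: int = 3,
    max_len: int = 200,
    count_probe: bool = True,
) -> AmpliconHit | None:
    """Locate the assay's amplicon on one reference sequence.

    Gaps are stripped before searching.  Both strands are scanned; the
    placement minimizing total primer mismatches, with each primer within
    ``max_mm`` and amplicon length <= ``max_len``, wins.  Multiple
    equal-score placements are reported via ``ambiguous``/``alternatives``.
    Returns None when no qualifying pair exists.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    template = strip_gaps(sequence.upper())
    n = len(template)
    candidates = []
    plus = _best_pair(template, oligos, max_mm, max_len)
    if plus is not None:
        candidates.append((plus[2] + plus[3], 1, plus))
    minus = _best_pair(_revcomp(template), oligos, max_mm, max_len)
    if minus is not None:
        candidates.append((minus[2] + minus[3], -1, minus))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], -c[1]))
    _, strand, (s0, e0, fmm, rmm, amb, alts) = candidates[0]
    if strand == -1:
        # map coordinates on the reverse complement back to the input
        s0, e0 = n - 1 - e0, n - 1 - s0
        alts = [(n - 1 - b, n - 1 - a) for a, b in alts]
    hit = AmpliconHit(
        species=label,
        start=s0 + 1,
        end=e0 + 1,
        length=e0 - s0 + 1,
        fwd_mismatches=fmm,
        rev_mismatches=rmm,
        strand=strand,
        ambiguous=amb,
        alternatives=[(a + 1, b + 1) for a, b in alts],
    )
    if count_probe:
        hit.probe_mismatches = _probe_mismatches(template, hit, oligos)
    return hit


def amplicon_sequence(sequence: str, hit: AmpliconHit) -> str:
    """Sense-strand amplicon string for a hit on its (gap-stripped) template."""
    template = strip_gaps(sequence.upper())
    sub = template[hit.start - 1: hit.end]
    return sub if hit.strand == 1 else _revcomp(sub)


def _probe_mismatches(template: str, hit: AmpliconHit, oligos: AssayOligos) -> int | None:
    """Best-placement loop mismatches inside the amplicon interior.

    The beacon loop may match either strand of the amplicon; the minimum
    over both orientations and all placements between the primer
    footprints is returned.  None when the loop does not fit.
    """
    amp = amplicon_sequence(template, hit)
    interior = amp[len(oligos.forward): len(amp) - len(oligos.reverse)]
    loop = oligos.probe_loop
    if len(loop) > len(interior):
        return None
    best = None
    for probe in (loop, _revcomp(loop)):
        for i in range(len(interior) - len(probe) + 1):
            mm = hamming_mismatches(probe, interior[i: i + len(probe)])
            if best is None or mm < best:
                best = mm
    return best


def probe_mismatch_table(
    refs: ReferenceSet,
    oligos: AssayOligos,
    max_mm: int = 3,
    max_len: int = 200,
) -> pd.DataFrame:
    """Per-record primer/probe mismatch report against a reference panel.

    Records with no qualifying amplicon (primer mismatches beyond
    ``max_mm``) are retained with ``alignable=False`` and NA counts — for
    a specificity screen that is itself the answer.  Columns: species,
    label, alignable, amplicon_start, amplicon_end, length, fwd_mm,
    rev_mm, probe_mm.
    """
    rows = []
    for label, seq in refs.records:
        hit = find_amplicon(label, seq, oligos, max_mm=max_mm, max_len=max_len)
        if hit is None or hit.probe_mismatches is None:
            rows.append({
                "species": refs.species_of(label), "label": label,
                "alignable": False, "amplicon_start": pd.NA,
                "amplicon_end": pd.NA, "length": pd.NA,
                "fwd_mm": pd.NA, "rev_mm": pd.NA, "probe_mm": pd.NA,
            })
        else:
            rows.append({
                "species": refs.species_of(label), "label": label,
                "alignable": True, "amplicon_start": hit.start,
                "amplicon_end": hit.end, "length": hit.length,
                "fwd_mm": hit.fwd_mismatches, "rev_mm": hit.rev_mismatches,
                "probe_mm": hit.probe_mismatches,
            })
    return pd.DataFrame(rows)


@dataclass
class DiagnosticSite:
    """An amplicon position fixed for different bases in two species."""

    amplicon_position: int  # 1-based bp within the amplicon
    allele_by_species: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.allele_by_species.values())) < 2:
            raise ValueError("a diagnostic site needs two distinct bases")


def find_diagnostic_snps(
    refs: ReferenceSet,
    oligos: AssayOligos,
    species_a: str,
    species_b: str,
    max_mm: int = 3,
) -> list[DiagnosticSite]:
    """Fixed nucleotide differences between two species within the amplicon.

    Each species' sequences are reduced to their amplicon strings (all must
    be the same length — the assay's amplicon is indel-free between these
    taxa); a position is diagnostic when every sequence of ``species_a``
    carries one base and every sequence of ``species_b`` a different base.
    Sorted ascending, 1-based within the amplicon.
    """
    amps: dict[str, list[str]] = {}
    for sp in (species_a, species_b):
        seqs = refs.by_species(sp)
        if not seqs:
            raise ValueError(f"no sequences labelled {sp!r} in the reference set")
        extracted = []
        for label, seq in seqs:
            hit = find_amplicon(label, seq, oligos, max_mm=max_mm, count_probe=False)
            if hit is not None:
                extracted.append(amplicon_sequence(seq, hit))
        if not extracted:
            raise ValueError(f"no sequence of {sp!r} spans the amplicon")
        amps[sp] = extracted
    lengths = {len(s) for seqs in amps.values() for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"amplicon lengths differ across sequences: {sorted(lengths)}")
    (length,) = lengths
    sites = []
    for pos in range(length):
        col_a = {s[pos] for s in amps[species_a]}
        col_b = {s[pos] for s in amps[species_b]}
        if len(col_a) == 1 and len(col_b) == 1 and col_a != col_b:
            sites.append(DiagnosticSite(
                amplicon_position=pos + 1,
                allele_by_species={species_a: col_a.pop(), species_b: col_b.pop()},
            ))
    return sites
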
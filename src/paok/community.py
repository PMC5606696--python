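"""Clone-library processing: OTU clustering at a fixed identity threshold,
clade assignment against a labelled *ppk1* reference panel, and per-run
clade/type composition tables.

Accumulibacter splits by *ppk1* phylogeny into Type I (clades IA–IE) and
Type II (clades IIA–IIH plus II-I).  A clone library for one enrichment run
is a small set of *ppk1* sequences; clones are grouped into operational
taxonomic units (OTUs) at 99 % identity, each OTU representative is assigned
to the closest reference clade, and the resulting per-clade clone counts give
the run's clade and type composition (integer percentages).

Identity convention (pinned and documented, since "99 % identity" alone does
not fix one): matches divided by the global-alignment length, gap columns
counting as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align

__all__ = [
    "CLADE_LABELS",
    "CloneLibrary",
    "Otu",
    "OtuSet",
    "CladeReferencePanel",
    "CladeAssignment",
    "CompositionTable",
    "pairwise_identity",
    "cluster_otus",
    "assign_clade",
    "composition",
]

#: Recognized Accumulibacter ppk1 clade vocabulary.
CLADE_LABELS: tuple[str, ...] = (
    "IA", "IB", "IC", "ID", "IE",
    "IIA", "IIB", "IIC", "IID", "IIE", "IIF", "IIG", "IIH", "II-I",
)

_ALPHABET = set("ACGTN")


def _validate_seq(seq: str, context: str) -> None:
    if not seq:
        raise ValueError(f"empty sequence for {context}")
    bad = set(seq.upper()) - _ALPHABET
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} in {context}")


@dataclass(frozen=True)
class CloneLibrary:
    """The clone sequences retrieved from one enrichment run."""

    run_id: str
    sequences: tuple[tuple[str, str], ...]  # (clone id, nucleotide sequence)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("clone library must be non-empty")
        ids = [cid for cid, _ in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("clone ids must be unique")
        for cid, seq in self.sequences:
            _validate_seq(seq, f"clone {cid!r}")
        object.__setattr__(
            self,
            "sequences",
            tuple((cid, seq.upper()) for cid, seq in self.sequences),
        )


@dataclass(frozen=True)
class Otu:
    representative_id: str
    representative_seq: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class OtuSet:
    otus: tuple[Otu, ...]

    @property
    def clone_to_otu(self) -> dict[str, int]:
        mapping: dict[str, int] = {}
        for i, otu in enumerate(self.otus):
            for cid in otu.members:
                mapping[cid] = i
        return mapping


@dataclass(frozen=True)
class CladeReferencePanel:
    """Labelled reference sequences, one (or more) per clade."""

    entries: tuple[tuple[str, str], ...]  # (clade label, sequence)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("reference panel must be non-empty")
        for label, seq in self.entries:
            if label not in CLADE_LABELS:
                raise ValueError(f"unknown clade label {label!r}")
            _validate_seq(seq, f"reference {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.entries)


@dataclass(frozen=True)
class CladeAssignment:
    label: str  # clade label or "unassigned"
    identity: float
    tie: bool = False


def _aligner() -> Align.PairwiseAligner:
    # Global alignment rewarding matches and penalizing gaps hard enough that
    # a point substitution is never traded for a gap pair.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


_GLOBAL_ALIGNER = _aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical columns under global alignment, in [0, 1].

    Gap columns count as mismatches (identity = matches / alignment length),
    so the measure is symmetric and equals the simple match fraction for
    equal-length ungapped alignments.
    """
    _validate_seq(seq_a, "seq_a")
    _validate_seq(seq_b, "seq_b")
    alignment = _GLOBAL_ALIGNER.align(seq_a.upper(), seq_b.upper())[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def cluster_otus(library: CloneLibrary, threshold: float = 0.99) -> OtuSet:
    """Greedy incremental OTU clustering at the given identity threshold.

    Clones are processed in input order; each joins the first existing OTU
    whose *representative* it matches at >= ``threshold``, otherwise it
    founds a new OTU with itself as representative.  Deterministic by
    construction; every clone lands in exactly one OTU.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    otus: list[tuple[str, str, list[str]]] = []  # (rep id, rep seq, members)
    for cid, seq in library.sequences:
        for rep_id, rep_seq, members in otus:
            if pairwise_identity(rep_seq, seq) >= threshold:
                members.append(cid)
                break
        else:
            otus.append((cid, seq, [cid]))
    return OtuSet(
        otus=tuple(
            Otu(representative_id=rid, representative_seq=rseq, members=tuple(m))
            for rid, rseq, m in otus
        )
    )


def assign_clade(
    representative: str,
    panel: CladeReferencePanel,
    min_identity: float = 0.85,
) -> CladeAssignment:
    """Assign an OTU representative to the closest reference clade.

    Returns the highest-identity panel label when that identity reaches
    ``min_identity``, else ``"unassigned"``.  Exact identity ties are broken
    by panel order and flagged.
    """
    _validate_seq(representative, "representative")
    best_label, best_identity, tie = "unassigned", -1.0, False
    for label, ref_seq in panel.entries:
        ident = pairwise_identity(representative, ref_seq)
        if ident > best_identity:
            best_label, best_identity, tie = label, ident, False
        elif ident == best_identity:
            tie = True
    if best_identity < min_identity:
        return CladeAssignment("unassigned", best_identity, tie)
    return CladeAssignment(best_label, best_identity, tie)


def _percent(count: int, total: int) -> int:
    # round half away from zero, matching how printed percentages are formed
    return int(count * 100.0 / total + 0.5)


@dataclass(frozen=True)
class CompositionTable:
    """Per-run clade counts, integer clade percentages and type percentages."""

    run_id: str
    counts: Mapping[str, int]
    fractions: Mapping[str, int]  # percent per clade
    type_fractions: Mapping[str, int]  # {"I": percent, "II": percent}
    n_clones: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "run_id": self.run_id,
                "clade": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [self.fractions[c] for c in self.counts],
            }
        )


def composition(assignments: Mapping[str, str], run_id: str) -> CompositionTable:
    """Tabulate clade counts and percentages from per-clone clade labels.

    ``assignments`` maps clone id to a clade label; clones labelled
    ``"unassigned"`` are excluded from the table.  Percentages are rounded to
    the nearest integer (8/13 -> 62 %); type percentages sum the clades whose
    label starts with "II" (Type II) versus the rest of Type I.
    """
    assigned = {
        cid: clade for cid, clade in assignments.items() if clade != "unassigned"
    }
    if not assigned:
        raise ValueError("no assigned clones to tabulate")
    for clade in assigned.values():
        if clade not in CLADE_LABELS:
            raise ValueError(f"unknown clade label {clade!r}")
    counts: dict[str, int] = {}
    for clade in assigned.values():
        counts[clade] = counts.get(clade, 0) + 1
    counts = dict(sorted(counts.items(), key=lambda kv: CLADE_LABELS.index(kv[0])))
    total = sum(counts.values())
    fractions = {clade: _percent(n, total) for clade, n in counts.items()}
    type_counts = {"I": 0, "II": 0}
    for clade, n in counts.items():
        type_counts["II" if clade.startswith("II") else "I"] += n
    type_fractions = {t: _percent(n, total) for t, n in type_counts.items()}
    return CompositionTable(
        run_id=run_id,
        counts=counts,
        fractions=fractions,
        type_fractions=type_fractions,
        n_clones=total,
    )
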
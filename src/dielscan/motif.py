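"""E-box motif localisation, alignment projection and conservation reporting.

The E-box (CACGTG) is the enhancer hexamer bound by CLOCK/BMAL1 dimers; its
conservation state across taxa is the first question the pipeline answers.
Sites are found on the gap-stripped reference sequence (the hexamer is its
own reverse complement, so one strand suffices; non-palindromic motifs are
searched on both strands), then projected through the alignment so every
taxon's residues at the homologous columns can be classified as conserved,
substituted, ambiguous or gapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from dielscan.io import Alignment, GAP, SampleMetadata, SequenceRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSite:
    """An exact motif match on the ungapped reference (0-based start)."""

    start: int
    strand: str = "+"


@dataclass(frozen=True)
class TaxonMotifState:
    """What one taxon shows at the projected motif columns."""

    observed: str
    status: str  # 'conserved' | 'substituted' | 'ambiguous' | 'gapped'
    substitutions: tuple[tuple[int, str, str], ...] = ()  # (offset, from, to)
    ambiguous_offsets: tuple[int, ...] = ()


@dataclass
class MotifReport:
    """One motif occurrence projected across all taxa."""

    motif_id: str
    ref_id: str
    motif: str
    ref_ungapped_start: int
    alignment_columns: tuple[int, ...]
    per_taxon: dict[str, TaxonMotifState] = field(default_factory=dict)


def find_motif_sites(record: SequenceRecord, motif: str = "CACGTG") -> list[MotifSite]:
    """All (possibly overlapping) exact matches on the gap-stripped sequence.

    Palindromic motifs (equal to their reverse complement, like CACGTG) are
    reported once on the plus strand; other motifs are searched on both
    strands with the strand recorded.
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    seq = record.ungapped
    sites = [MotifSite(i, "+") for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]
    rc = reverse_complement(motif)
    if rc != motif:
        sites += [
            MotifSite(i, "-")
            for i in range(len(seq) - len(motif) + 1)
            if seq[i : i + len(motif)] == rc
        ]
        sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def _ungapped_to_columns(residues: str) -> list[int]:
    """Alignment column index of each ungapped position of this row."""
    return [c for c, ch in enumerate(residues) if ch != GAP]


def classify_observed(observed: str, motif: str) -> TaxonMotifState:
    if GAP in observed:
        return TaxonMotifState(observed=observed, status="gapped")
    amb = tuple(i for i, ch in enumerate(observed) if ch not in "ACGT")
    if amb:
        return TaxonMotifState(observed=observed, status="ambiguous", ambiguous_offsets=amb)
    if observed == motif:
        return TaxonMotifState(observed=observed, status="conserved")
    subs = tuple((i, motif[i], observed[i]) for i in range(len(motif)) if observed[i] != motif[i])
    return TaxonMotifState(observed=observed, status="substituted", substitutions=subs)


def motif_conservation(
    alignment: Alignment, ref_id: str, motif: str = "CACGTG", motif_prefix: str = "E-box"
) -> list[MotifReport]:
    """Locate every motif hit on the reference and classify all taxa at it.

    Reference hits are numbered 1..k in reference order (``E-box_1`` ...).
    The hit's ungapped positions are mapped to alignment columns by skipping
    the reference row's gap columns, and each taxon's characters at those
    columns are classified against the motif.
    """
    ref = alignment[ref_id]
    col_of = _ungapped_to_columns(ref.residues)
    reports: list[MotifReport] = []
    for k, site in enumerate(find_motif_sites(ref, motif), start=1):
        cols = tuple(col_of[site.start + o] for o in range(len(motif)))
        rep = MotifReport(
            motif_id=f"{motif_prefix}_{k}",
            ref_id=ref_id,
            motif=motif.upper(),
            ref_ungapped_start=site.start,
            alignment_columns=cols,
        )
        for rec in alignment.records:
            observed = "".join(rec.residues[c] for c in cols)
            rep.per_taxon[rec.id] = classify_observed(observed, motif.upper())
        reports.append(rep)
    return reports


def trait_partition(
    report: MotifReport, metadata: SampleMetadata, trait: str = "behavior"
) -> tuple[dict[int, bool], bool]:
    """Does any motif position split the taxa perfectly by trait level?

    For each motif offset, taxa with a gap anywhere in the motif are excluded
    (absence of the site is not an allele), as are taxa whose character at
    that offset is ambiguous.  The offset partitions the trait iff no
    character is shared between trait levels and at least two levels carry
    characters.  Returns (per-offset verdicts, any-offset verdict).
    """
    length = len(report.motif)
    per_offset: dict[int, bool] = {}
    for off in range(length):
        chars_by_level: dict[str, set[str]] = {}
        for sid, state in report.per_taxon.items():
            if sid not in metadata.rows or not metadata.rows[sid].in_primate_tests:
                continue
            if state.status == "gapped":
                continue
            ch = state.observed[off]
            if ch not in "ACGT":
                continue
            level = getattr(metadata.rows[sid], trait)
            chars_by_level.setdefault(level, set()).add(ch)
        if len(chars_by_level) < 2:
            per_offset[off] = False
            continue
        levels = list(chars_by_level.values())
        shared = False
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                if levels[i] & levels[j]:
                    shared = True
        per_offset[off] = not shared
    return per_offset, any(per_offset.values())


def write_motif_table(reports: list[MotifReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\ttaxon\tobserved\tstatus\tdetail\n")
        for rep in reports:
            for sid, st in rep.per_taxon.items():
                if st.status == "substituted":
                    detail = ";".join(f"{o}:{f}>{t}" for o, f, t in st.substitutions)
                elif st.status == "ambiguous":
                    detail = ";".join(str(o) for o in st.ambiguous_offsets)
                else:
                    detail = "."
                fh.write(f"{rep.motif_id}\t{sid}\t{st.observed}\t{st.status}\t{detail}\n")


def write_motif_bed(reports: list[MotifReport], path) -> None:
    """Motif locations in reference ungapped coordinates (BED, 0-based half-open)."""
    with open(path, "w") as fh:
        for rep in reports:
            fh.write(
                f"{rep.ref_id}\t{rep.ref_ungapped_start}\t{rep.ref_ungapped_start + len(rep.motif)}\t{rep.motif_id}\n"
            )
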
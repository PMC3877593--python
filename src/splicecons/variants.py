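"""Classification of splice-variant transcripts against their canonical form.

Events recognised, matching the mechanisms seen in Mouse/Human cytokine
receptor transcript variants: skipping of one or more consecutive exons
(the acceptor site upstream of each skipped exon is silenced), and
alternative acceptor (3'ss) or donor (5'ss) use shifting one exon boundary
by a signed nucleotide offset. Everything else (intron retention,
alternative first/last exons, exon inclusion relative to the reference) is
surfaced as ``unrecognized`` rather than silently dropped or mislabeled.

Coordinates are 1-based closed intervals on the gene (sense-strand) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

EVENT_KINDS = ("exon_skipping", "alt_3ss", "alt_5ss", "unrecognized")


@dataclass(frozen=True)
class TranscriptStructure:
    """Ordered exon intervals of one transcript on the gene axis.

    ``splice_hexes`` optionally carries (donor hex, acceptor hex) sequence
    context per intron for annotating events; it is never required.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[tuple[int, int], ...]
    splice_hexes: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("a transcript must have at least one exon")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"invalid exon interval ({start}, {end})")
            if start <= prev_end:
                raise ValueError("exons must be sorted, disjoint and increasing")
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_length(self, index: int) -> int:
        """Length of the 1-based ``index``-th exon."""
        start, end = self.exons[index - 1]
        return end - start + 1

    @property
    def total_exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass(frozen=True)
class VariantEvent:
    """One difference between a variant and its canonical transcript.

    ``canonical_exons`` is the 1-based inclusive range of canonical exons
    involved (a single exon for alt events). ``offset_nt`` is signed,
    negative meaning the variant splice site lies upstream of the canonical
    one; it is None for skipping and unrecognized events.
    """

    kind: str
    gene_id: str
    canonical_exons: tuple[int, int]
    length_change_nt: int
    offset_nt: int | None = None
    frame_preserved: bool = field(init=False)
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind in ("alt_3ss", "alt_5ss"):
            if self.offset_nt is None or self.offset_nt == 0:
                raise ValueError("alternative-site events need a nonzero offset")
        object.__setattr__(self, "frame_preserved", self.length_change_nt % 3 == 0)


def _overlaps(x: tuple[int, int], y: tuple[int, int]) -> bool:
    return x[0] <= y[1] and y[0] <= x[1]


def classify_variant(
    canonical: TranscriptStructure, variant: TranscriptStructure
) -> list[VariantEvent]:
    """Compare a variant transcript against the canonical on the gene axis.

    Canonical exons with no overlapping variant exon become exon-skipping
    events (consecutive skips merged); a variant exon sharing exactly one
    boundary with its canonical partner becomes an alternative-acceptor
    (left boundary differs) or alternative-donor (right boundary differs)
    event with a signed offset. Anything else is reported as unrecognized.
    Events come back in genomic order.
    """
    if canonical.gene_id != variant.gene_id:
        raise ValueError("canonical and variant must lie on the same gene axis")
    gene = canonical.gene_id
    events: list[tuple[int, VariantEvent]] = []

    cmatch: dict[int, list[int]] = {i: [] for i in range(canonical.n_exons)}
    vmatch: dict[int, list[int]] = {j: [] for j in range(variant.n_exons)}
    for i, ce in enumerate(canonical.exons):
        for j, ve in enumerate(variant.exons):
            if _overlaps(ce, ve):
                cmatch[i].append(j)
                vmatch[j].append(i)

    # --- skipped canonical exons, consecutive runs merged -----------------
    skipped = [i for i in range(canonical.n_exons) if not cmatch[i]]
    run_start = None
    for i in skipped + [-2]:
        if run_start is None:
            run_start, run_end = i, i
        elif i == run_end + 1:
            run_end = i
        else:
            length = sum(canonical.exon_length(k + 1) for k in range(run_start, run_end + 1))
            events.append(
                (
                    canonical.exons[run_start][0],
                    VariantEvent(
                        kind="exon_skipping",
                        gene_id=gene,
                        canonical_exons=(run_start + 1, run_end + 1),
                        length_change_nt=-length,
                    ),
                )
            )
            run_start, run_end = (i, i) if i >= 0 else (None, None)

    # --- boundary comparison of matched exons -----------------------------
    for j, ve in enumerate(variant.exons):
        owners = vmatch[j]
        if not owners:
            events.append(
                (
                    ve[0],
                    VariantEvent(
                        kind="unrecognized",
                        gene_id=gene,
                        canonical_exons=(0, 0),
                        length_change_nt=ve[1] - ve[0] + 1,
                        note=f"variant exon {j + 1} overlaps no canonical exon",
                    ),
                )
            )
            continue
        if len(owners) > 1 or len(cmatch[owners[0]]) > 1:
            events.append(
                (
                    ve[0],
                    VariantEvent(
                        kind="unrecognized",
                        gene_id=gene,
                        canonical_exons=(min(owners) + 1, max(owners) + 1),
                        length_change_nt=(ve[1] - ve[0] + 1)
                        - sum(canonical.exon_length(i + 1) for i in owners),
                        note="non one-to-one exon correspondence",
                    ),
                )
            )
            continue
        i = owners[0]
        ce = canonical.exons[i]
        left_diff = ve[0] - ce[0]
        right_diff = ve[1] - ce[1]
        if left_diff == 0 and right_diff == 0:
            continue
        if left_diff != 0 and right_diff == 0:
            events.append(
                (
                    ve[0],
                    VariantEvent(
                        kind="alt_3ss",
                        gene_id=gene,
                        canonical_exons=(i + 1, i + 1),
                        offset_nt=left_diff,
                        length_change_nt=-left_diff,
                    ),
                )
            )
        elif left_diff == 0 and right_diff != 0:
            events.append(
                (
                    ve[0],
                    VariantEvent(
                        kind="alt_5ss",
                        gene_id=gene,
                        canonical_exons=(i + 1, i + 1),
                        offset_nt=right_diff,
                        length_change_nt=right_diff,
                    ),
                )
            )
        else:
            events.append(
                (
                    ve[0],
                    VariantEvent(
                        kind="unrecognized",
                        gene_id=gene,
                        canonical_exons=(i + 1, i + 1),
                        length_change_nt=(ve[1] - ve[0] + 1) - canonical.exon_length(i + 1),
                        note="both exon boundaries differ",
                    ),
                )
            )
    events.sort(key=lambda t: t[0])
    return [e for _, e in events]


def variability_summary(
    classifications: Iterable[Sequence[VariantEvent]],
    canonical_site_counts: tuple[int, int],
) -> tuple[float, float]:
    """Fractions of variable donor (5'ss) and acceptor (3'ss) sites.

    A canonical acceptor is variable when any variant silences it (the
    downstream exon is skipped) or replaces it (alternative acceptor);
    similarly a donor for alternative-donor events. A site hit by several
    variants counts once. Returns ``(fraction_5ss, fraction_3ss)`` over the
    supplied canonical site totals.
    """
    n_5ss, n_3ss = canonical_site_counts
    sites5: set[tuple[str, int]] = set()
    sites3: set[tuple[str, int]] = set()
    for events in classifications:
        for ev in events:
            if ev.kind == "exon_skipping":
                for exon in range(ev.canonical_exons[0], ev.canonical_exons[1] + 1):
                    sites3.add((ev.gene_id, exon))
            elif ev.kind == "alt_3ss":
                sites3.add((ev.gene_id, ev.canonical_exons[0]))
            elif ev.kind == "alt_5ss":
                sites5.add((ev.gene_id, ev.canonical_exons[0]))
    if len(sites5) > n_5ss or len(sites3) > n_3ss:
        raise ValueError("site totals smaller than the number of affected sites")
    frac5 = len(sites5) / n_5ss if n_5ss else 0.0
    frac3 = len(sites3) / n_3ss if n_3ss else 0.0
    return frac5, frac3


def events_frame(
    pairs: Iterable[tuple[str, Sequence[VariantEvent]]]
) -> pd.DataFrame:
    """TSV-ready table of events, one row per (variant transcript, event)."""
    rows = []
    for variant_id, events in pairs:
        for ev in events:
            rows.append(
                {
                    "gene": ev.gene_id,
                    "variant": variant_id,
                    "kind": ev.kind,
                    "exons": f"{ev.canonical_exons[0]}-{ev.canonical_exons[1]}",
                    "offset": "" if ev.offset_nt is None else ev.offset_nt,
                    "length_change": ev.length_change_nt,
                    "frame_preserved": ev.frame_preserved,
                    "note": ev.note,
                }
            )
    return pd.DataFrame(rows)


def read_transcripts_tsv(path) -> dict[str, TranscriptStructure]:
    """Read transcript structures from a TSV with columns
    ``gene_id transcript_id exon_index start end``."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "transcript_id", "exon_index", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transcript table lacks columns: {sorted(missing)}")
    out = {}
    for (gene, tid), grp in df.groupby(["gene_id", "transcript_id"], sort=False):
        grp = grp.sort_values("exon_index")
        exons = tuple((int(r.start), int(r.end)) for r in grp.itertuples())
        out[str(tid)] = TranscriptStructure(str(tid), str(gene), exons)
    return out
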
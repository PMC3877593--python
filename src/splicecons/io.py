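"""Reading, validation and pairing of orthologous intron sequences.

Introns are supplied as two FASTA files (one per species), already oriented
5'->3' on the mRNA sense strand, together with a TSV manifest pairing the
records: one row per orthologous couple with columns
``gene_id  intron_index  id_a  id_b``.

Sequences are normalised to uppercase DNA (U -> T) on read; the canonical
GT...AG flags are always recomputed from the sequence itself, never trusted
from the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Bases allowed inside an intron sequence after normalisation.
VALID_ALPHABET = frozenset("ACGTN")

#: Minimum intron length so the initial and terminal hexanucleotides are
#: disjoint (6 + 6). Shorter introns are dropped by :func:`filter_pairs`.
MIN_INTRON_LENGTH = 12

MANIFEST_COLUMNS = ("gene_id", "intron_index", "id_a", "id_b")


def normalize_sequence(seq: str) -> str:
    """Uppercase, convert RNA U to T, and validate the alphabet."""
    s = str(seq).strip().upper().replace("U", "T")
    bad = set(s) - VALID_ALPHABET
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return s


def is_canonical(seq: str) -> bool:
    """True when the intron begins with GT and ends with AG."""
    return len(seq) >= 4 and seq.startswith("GT") and seq.endswith("AG")


@dataclass(frozen=True)
class OrthologousIntronPair:
    """One orthologous couple of intron sequences (species A / species B).

    ``canonical_a`` / ``canonical_b`` are recomputed from the sequences at
    construction time.
    """

    gene_id: str
    intron_index: int
    seq_a: str
    seq_b: str
    canonical_a: bool = field(init=False)
    canonical_b: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.intron_index < 1:
            raise ValueError("intron_index must be >= 1")
        object.__setattr__(self, "seq_a", normalize_sequence(self.seq_a))
        object.__setattr__(self, "seq_b", normalize_sequence(self.seq_b))
        object.__setattr__(self, "canonical_a", is_canonical(self.seq_a))
        object.__setattr__(self, "canonical_b", is_canonical(self.seq_b))

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene_id, self.intron_index)


@dataclass(frozen=True)
class AnalysisConfig:
    """Run-level parameters for the conservation analysis.

    ``n_pairs_expected`` defaults to 216 orthologous couples, the sample
    size of the Mouse/Human cytokine-receptor intron dataset the defaults
    throughout this package are modelled on.
    """

    n_pairs_expected: int = 216
    window: int = 50
    alpha: float = 0.05
    require_canonical: bool = True

    def __post_init__(self) -> None:
        if self.window < 6:
            raise ValueError("window must be >= 6")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate the pairing manifest TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "id_a": str, "id_b": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns: {missing}")
    dup = df.duplicated(subset=["gene_id", "intron_index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (gene_id, intron_index) in manifest: "
            f"({row.gene_id!r}, {int(row.intron_index)})"
        )
    return df


def read_ortholog_pairs(
    fasta_a: str | Path, fasta_b: str | Path, manifest: str | Path
) -> list[OrthologousIntronPair]:
    """Assemble intron couples from two FASTA files and a manifest.

    Returns one pair per manifest row, in manifest order. A manifest row
    referencing an ID absent from its FASTA is a hard error naming the row.
    """
    seqs_a = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_a), "fasta")}
    seqs_b = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_b), "fasta")}
    df = read_manifest(manifest)
    pairs: list[OrthologousIntronPair] = []
    for i, row in df.iterrows():
        for sid, pool, which in ((row.id_a, seqs_a, "A"), (row.id_b, seqs_b, "B")):
            if sid not in pool:
                raise KeyError(
                    f"manifest row {i + 1} ({row.gene_id}, intron "
                    f"{int(row.intron_index)}): ID {sid!r} not found in FASTA {which}"
                )
        pairs.append(
            OrthologousIntronPair(
                gene_id=str(row.gene_id),
                intron_index=int(row.intron_index),
                seq_a=seqs_a[row.id_a],
                seq_b=seqs_b[row.id_b],
            )
        )
    return pairs


def _hexes_clean(seq: str) -> bool:
    return VALID_ALPHABET.issuperset(seq[:6]) and "N" not in seq[:6] and "N" not in seq[-6:]


def filter_pairs(
    pairs: Sequence[OrthologousIntronPair], config: AnalysisConfig | None = None
) -> list[OrthologousIntronPair]:
    """Drop couples unusable for the hexanucleotide analysis.

    A couple is dropped when either member is shorter than 12 nt, contains N
    inside either terminal hexanucleotide, or (with ``require_canonical``)
    fails the GT...AG check. Each drop is logged with its reason; an empty
    result is an error because every downstream statistic is undefined.
    """
    config = config or AnalysisConfig()
    kept: list[OrthologousIntronPair] = []
    for p in pairs:
        reason = None
        if len(p.seq_a) < MIN_INTRON_LENGTH or len(p.seq_b) < MIN_INTRON_LENGTH:
            reason = f"length < {MIN_INTRON_LENGTH}"
        elif not (_hexes_clean(p.seq_a) and _hexes_clean(p.seq_b)):
            reason = "N inside a terminal hexanucleotide"
        elif config.require_canonical and not (p.canonical_a and p.canonical_b):
            reason = "non-canonical (not GT...AG)"
        if reason is None:
            kept.append(p)
        else:
            logger.info("dropping (%s, intron %d): %s", p.gene_id, p.intron_index, reason)
    if not kept:
        raise ValueError("no intron couples survive filtering; statistics undefined")
    return kept


def write_ortholog_pairs(
    pairs: Sequence[OrthologousIntronPair],
    fasta_a: str | Path,
    fasta_b: str | Path,
    manifest: str | Path,
) -> None:
    """Write a pair set back to the FASTA x2 + manifest format it is read from."""
    recs_a, recs_b, rows = [], [], []
    for p in pairs:
        ida = f"{p.gene_id}_i{p.intron_index}_a"
        idb = f"{p.gene_id}_i{p.intron_index}_b"
        recs_a.append(SeqRecord(Seq(p.seq_a), id=ida, description=""))
        recs_b.append(SeqRecord(Seq(p.seq_b), id=idb, description=""))
        rows.append((p.gene_id, p.intron_index, ida, idb))
    SeqIO.write(recs_a, str(fasta_a), "fasta")
    SeqIO.write(recs_b, str(fasta_b), "fasta")
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest, sep="\t", index=False
    )


def pairs_table(pairs: Iterable[OrthologousIntronPair]) -> pd.DataFrame:
    """Tabular summary of a pair set (one row per couple)."""
    rows = [
        {
            "gene_id": p.gene_id,
            "intron_index": p.intron_index,
            "hex5_a": p.seq_a[:6],
            "hex5_b": p.seq_b[:6],
            "hex3_a": p.seq_a[-6:],
            "hex3_b": p.seq_b[-6:],
            "canonical_a": p.canonical_a,
            "canonical_b": p.canonical_b,
            "len_a": len(p.seq_a),
            "len_b": len(p.seq_b),
        }
        for p in pairs
    ]
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path: str | Path, float_fmt: str = "%.4f") -> None:
    """Write a TSV with fixed float formatting so outputs are byte-stable."""
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt)
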
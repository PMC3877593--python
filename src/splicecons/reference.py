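"""Published reference values from the 216 Mouse/Human cytokine-receptor
orthologous intron couples that this package's defaults are modelled on.

These are the per-position base frequencies, random and actual conservation
values, and hexanucleotide usage frequencies reported for that dataset. They
serve two purposes: as inputs for desk-checkable recomputations of the
random-association motif probabilities (the raw sequences themselves are not
redistributable), and as defaults for the synthetic-data generator.

All values are stored exactly as printed (percentages to the published
precision); fractions are derived by dividing by 100.
"""

from __future__ import annotations

from .census import FIVE_PRIME, THREE_PRIME
from .conservation import ConservationTable

#: Number of orthologous intron couples in the reference dataset.
REFERENCE_N = 216

# Per (variable position, base): % in species A (Mouse), % in species B
# (Human), random conservation %, actual conservation %.
_FIVE_PRIME_TABLE = {
    (3, "A"): (59.7, 57.5, 34.03, 50.93),
    (3, "C"): (1.9, 2.3, 0.04, 1.85),
    (3, "G"): (37.0, 38.4, 14.21, 30.09),
    (3, "T"): (1.4, 2.3, 0.03, 1.39),
    (4, "A"): (82.4, 81.0, 66.74, 77.78),
    (4, "C"): (2.8, 2.8, 0.08, 2.31),
    (4, "G"): (6.9, 8.3, 0.57, 4.17),
    (4, "T"): (7.9, 7.9, 0.62, 6.02),
    (5, "A"): (7.9, 7.4, 0.58, 6.48),
    (5, "C"): (1.4, 1.8, 0.03, 0.93),
    (5, "G"): (85.2, 84.3, 71.82, 82.41),
    (5, "T"): (5.5, 6.5, 0.36, 3.70),
    (6, "A"): (21.8, 24.1, 5.25, 16.20),
    (6, "C"): (11.6, 7.4, 0.86, 3.70),
    (6, "G"): (16.6, 19.9, 3.30, 8.33),
    (6, "T"): (50.0, 48.6, 24.30, 45.37),
}

_THREE_PRIME_TABLE = {
    (1, "A"): (5.1, 5.6, 0.29, 2.31),
    (1, "C"): (35.2, 33.8, 11.9, 23.61),
    (1, "G"): (8.3, 4.6, 0.38, 3.70),
    (1, "T"): (51.4, 56.0, 28.78, 42.59),
    (2, "A"): (7.9, 9.3, 0.73, 5.09),
    (2, "C"): (25.9, 22.2, 5.75, 13.89),
    (2, "G"): (8.3, 8.3, 0.69, 5.09),
    (2, "T"): (57.9, 60.2, 34.86, 48.61),
    (3, "A"): (27.3, 26.9, 7.34, 17.13),
    (3, "C"): (27.3, 29.1, 7.94, 16.67),
    (3, "G"): (19.9, 21.3, 4.24, 9.26),
    (3, "T"): (25.5, 22.7, 5.79, 16.67),
    (4, "A"): (7.4, 7.0, 0.52, 6.02),
    (4, "C"): (63.0, 59.7, 37.6, 50.46),
    (4, "G"): (0.0, 0.0, 0.00, 0.00),
    (4, "T"): (29.6, 33.3, 9.86, 20.83),
}


def _table(end: str, raw: dict) -> ConservationTable:
    return ConservationTable.from_values(
        end=end,
        n=REFERENCE_N,
        freq_a={k: v[0] / 100.0 for k, v in raw.items()},
        freq_b={k: v[1] / 100.0 for k, v in raw.items()},
        random_cons={k: v[2] / 100.0 for k, v in raw.items()},
        actual_cons={k: v[3] / 100.0 for k, v in raw.items()},
    )


def reference_conservation_table(end: str) -> ConservationTable:
    """The published per-position conservation table for one intron end."""
    if end == FIVE_PRIME:
        return _table(FIVE_PRIME, _FIVE_PRIME_TABLE)
    if end == THREE_PRIME:
        return _table(THREE_PRIME, _THREE_PRIME_TABLE)
    raise ValueError(f"unknown end {end!r}")


#: Published actual-conservation position totals (fractions), in
#: hexanucleotide position order (5': positions 3-6; 3': h1-h4).
REFERENCE_POSITION_TOTALS = {
    FIVE_PRIME: (0.8426, 0.9028, 0.9352, 0.736),
    THREE_PRIME: (0.7221, 0.7268, 0.5973, 0.7731),
}

#: Background identity plateaus of the intron body (fractions): 5' body
#: (positions 7-50), 3' near segment (positions 7-21 from the end) and
#: 3' far segment (positions 22-50 from the end).
REFERENCE_PLATEAUS = {"five_body": 0.554, "three_near": 0.631, "three_far": 0.560}

#: Most frequent donor hexanucleotides (species-averaged %); remaining
#: usage mass is unprinted and spread uniformly by the generator.
REFERENCE_HEX5_USAGE = {
    "GTGAGT": 18.5,
    "GTAAGT": 18.1,
    "GTAAGA": 8.8,
    "GTGAGA": 5.6,
    "GTGAGG": 5.6,
    "GTAAGG": 4.4,
    "GTAAGC": 3.5,
}

#: Most frequent acceptor hexanucleotides (species-averaged %).
REFERENCE_HEX3_USAGE = {
    "TTTCAG": 6.9,
    "CTGCAG": 6.3,
    "TTTTAG": 5.6,
    "TTGCAG": 5.3,
    "TTCTAG": 4.9,
    "CCACAG": 3.9,
    "TTCCAG": 3.9,
}

#: The worked single-position example from the reference analysis: marginal
#: frequencies of A at donor position 3 (species A, species B) as used in
#: that calculation. Note the slight internal inconsistency in the source:
#: the worked example uses 0.570 for species B while the composition table
#: prints 57.5; the example's own inputs are kept here for reproducing it.
WORKED_EXAMPLE_POS3_A = (0.597, 0.570)
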
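"""One-off generator for the bundled synthetic domain seed alignments.

Writes 8-sequence gapped alignments for the four domain models (AP2, B3,
HATPase_c, HSP90) under src/legfam/data/.  Each alignment is the domain
consensus plus seven copies mutated at ~8% of positions, with three
mostly-gap inserted columns so that profile building has gap columns to
drop.  Deterministic; re-running reproduces the committed files.

The AP2 consensus is laid out on the canonical 58-position frame used for
AP2-domain residue numbering: position 14 (A/V), position 19 (D/E), the
WLG element at 27-29 and the RAYD element at 39-42.
"""
from __future__ import annotations

import pathlib

import numpy as np

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "legfam" / "data"

AA = "ACDEFGHIKLMNPQRSTVWY"

CONSENSUS = {
    # canonical 58-aa AP2/ERF DNA-binding domain frame (ERF-type: A14, D19)
    "AP2": "KYRGVRQRPWGKWAAEIRDPKKAARVWLGTFDTAEAAARAYDEAALRFKGNKAKLNFP",
    "B3": "RFFKVLLPGDVSDRMRIPPAFARHLDGRLPERVTLRGPSGAEWPVELTERDGHVYLQRGW",
    "HATPase_c": (
        "ETFAFNADIRQLMSLIINTVYSNKEIFLRELISNASDALDKLRYESLTDPSKLDSGKDLEIRIIPDKTNN"
    ),
    "HSP90": (
        "KVIVTDRIVDSPCCLVTGEYGWTANMERIMKAQALRDTSTMGYMAAKKHLEINPDHPIVKELRERVEADE"
        "NDKAVKDLVL"
    ),
}

# interior columns (0-based, on the consensus frame) after which a mostly-gap
# column is inserted; chosen away from the conserved AP2 landmarks
GAP_INSERTS = {
    "AP2": [9, 24, 49],
    "B3": [11, 30, 50],
    "HATPase_c": [14, 35, 60],
    "HSP90": [19, 44, 69],
}

N_SEQS = 8
MUT_FRACTION = 0.08


def build(name: str, rng: np.random.Generator) -> list[str]:
    """Consensus row plus seven variants.  Every column carries exactly one
    designated alternative residue in two of the eight rows, so each column
    has a well-supported second-most-frequent residue: divergent family
    members (alternative residues at many columns) still score positively
    against the resulting profile while sharing little identity with the
    consensus."""
    cons = CONSENSUS[name]
    rows = [list(cons) for _ in range(N_SEQS)]
    for j, c in enumerate(cons):
        alt_choices = [a for a in AA if a != c]
        alt = alt_choices[rng.integers(len(alt_choices))]
        r1 = 1 + (j % (N_SEQS - 1))
        r2 = 1 + ((j + 3) % (N_SEQS - 1))
        if r2 == r1:
            r2 = 1 + ((j + 4) % (N_SEQS - 1))
        rows[r1][j] = alt
        rows[r2][j] = alt
    rows = ["".join(r) for r in rows]
    # column majority must remain the consensus residue everywhere
    for j, c in enumerate(cons):
        col = [r[j] for r in rows]
        assert col.count(c) >= 5, f"{name} col {j}: consensus lost"
    # insert mostly-gap columns: residue in 2 random rows, '-' elsewhere
    cols = [list(col) for col in zip(*rows)]
    for offset, j in enumerate(sorted(GAP_INSERTS[name])):
        keep = rng.choice(N_SEQS, size=2, replace=False)
        newcol = ["-"] * N_SEQS
        for k in keep:
            newcol[k] = AA[rng.integers(len(AA))]
        cols.insert(j + 1 + offset, newcol)
    # a sprinkle of isolated gaps in non-consensus rows (stays <50% per column)
    n_cols = len(cols)
    for _ in range(4):
        j = int(rng.integers(n_cols))
        i = int(rng.integers(1, N_SEQS))
        if sum(c == "-" for c in cols[j]) <= 1:
            cols[j][i] = "-"
    return ["".join(row) for row in zip(*cols)]


def main() -> None:
    rng = np.random.default_rng(20160123)
    for name in CONSENSUS:
        rows = build(name, rng)
        path = DATA / f"{name.lower()}_seed.synthetic.afa"
        with open(path, "w") as fh:
            for i, row in enumerate(rows, start=1):
                fh.write(f">{name}_seed_{i:02d} synthetic seed alignment row\n")
                fh.write(row + "\n")
        print(f"{path.name}: {len(rows)} seqs x {len(rows[0])} cols "
              f"(consensus {len(CONSENSUS[name])})")


if __name__ == "__main__":
    main()
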
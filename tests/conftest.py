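import numpy as np
import pandas as pd
import pytest

from plastideg.residues import STANDARD_RESIDUES


def orf_table(rows):
    """Build an ORF table from compact row dicts.

    Each row: dict with coverage, length, optional class/genus/is_rpsC and
    either ``seq`` (string, residue counts derived) or explicit residue
    counts. Length defaults to the sequence length.
    """
    out = []
    for i, row in enumerate(rows):
        seq = row.pop("seq", None)
        counts = {r: 0 for r in STANDARD_RESIDUES}
        nonstandard = 0
        if seq is not None:
            for ch in seq.upper():
                if ch in counts:
                    counts[ch] += 1
                else:
                    nonstandard += 1
        for r in STANDARD_RESIDUES:
            if r in row:
                counts[r] = row.pop(r)
        rec = {
            "orf_id": row.pop("orf_id", f"orf{i}"),
            "scaffold_id": row.pop("scaffold_id", f"scf{i}"),
            "coverage": row.pop("coverage", 1.0),
            "length": row.pop(
                "length", len(seq) if seq is not None else sum(counts.values())
            ),
            "class": row.pop("class", "Gammaproteobacteria"),
            "genus": row.pop("genus", f"Genus{i}"),
            "is_rpsC": row.pop("is_rpsC", False),
            "nonstandard": row.pop("nonstandard", nonstandard),
        }
        assert not row, f"unused keys: {row}"
        rec.update(counts)
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
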
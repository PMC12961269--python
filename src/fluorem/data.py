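"""Bundled synthetic fixtures.

The five-record toy database stands in for a small mixture of purified
proteins (the classic small-scale benchmark uses PSME4, HBA2, HBB, PSME3
and PSMB10); the sequences here are synthetic — random amino-acid chains
with realistic tryptic-site and label-residue frequencies — so no external
database is needed for tests or examples.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .peptidome import LabelingScheme

# glutamate/aspartate, cysteine, tyrosine — a common three-channel scheme
DEFAULT_SCHEME = LabelingScheme(
    channels=(frozenset("DE"), frozenset("C"), frozenset("Y"))
)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# roughly uniprot-like composition, boosted K/R so tryptic peptides are short
_WEIGHTS = np.array([
    7.0, 2.0, 5.4, 6.8, 3.9, 7.1, 2.3, 5.3, 5.8, 9.7,
    2.4, 4.1, 4.7, 4.0, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9,
])


def synthetic_proteins(
    n_proteins: int = 5, length: int = 200, seed: int = 20260101
) -> list[tuple[str, str]]:
    """Deterministic synthetic protein records ``[(id, sequence), ...]``."""
    rng = np.random.default_rng(seed)
    w = _WEIGHTS / _WEIGHTS.sum()
    records = []
    for i in range(n_proteins):
        seq = "".join(rng.choice(_AA, size=length, p=w))
        records.append((f"SYNPROT{i + 1}", seq))
    return records


def write_toy_fasta(path: str | Path, n_proteins: int = 5,
                    length: int = 200, seed: int = 20260101) -> Path:
    """Write the synthetic toy FASTA (60-column wrapped) and return its path."""
    path = Path(path)
    with open(path, "w") as fh:
        for pid, seq in synthetic_proteins(n_proteins, length, seed):
            fh.write(f">{pid} synthetic toy protein\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j:j + 60] + "\n")
    return path
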
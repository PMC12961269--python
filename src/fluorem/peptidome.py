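"""Digestion, dye labeling, and the fluorescence-string dictionary.

A fluorosequencing experiment observes peptides only through the positions of
their fluorescent dyes.  Two peptides that carry the same dye pattern are
indistinguishable; the pattern is called a *fluorescence string*.  This module
turns a protein database plus a labeling scheme (protease + one amino-acid set
per dye channel) into the finite dictionary of fluorescence strings the
database can produce, together with per-protein peptide counts ``c(y, f)``.

Peptides with no labelable residue all collapse into the single null string
``f_null``, which is never observable on the instrument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from scipy import sparse

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = set("BZXU")
UNLABELED = "."

_PROTEASES = {
    # name -> (residues cleaved after, residues blocking when next)
    "trypsin": (set("KR"), set("P")),
}


@dataclass(frozen=True)
class LabelingScheme:
    """Dye channels and digestion rule defining the fluorescence-string map.

    Parameters
    ----------
    channels
        Ordered dye channels; each is the set of amino acids labeled by that
        channel's fluorophore.  Channels must be pairwise disjoint and at
        least one must be non-empty.
    protease
        Digestion rule identifier.  Only ``"trypsin"`` (cleave C-terminal to
        K/R except before P) is currently built in.
    missed_cleavages
        Number of allowed missed cleavage sites; 0 yields a complete digest.
    allow_ambiguous
        If True, non-standard residues (B, Z, X, U) are accepted and treated
        as unlabelable; otherwise they raise ``ValueError``.
    max_cycles
        If set, only the first ``max_cycles`` positions of a peptide are kept
        positionally; dyes beyond them are pooled into unordered per-channel
        counts (emulating an instrument that runs a fixed number of Edman
        cycles).  ``None`` (default) keeps the full positional pattern, the
        strictest peptide equivalence.
    """

    channels: tuple[frozenset[str], ...]
    protease: str = "trypsin"
    missed_cleavages: int = 0
    allow_ambiguous: bool = False
    max_cycles: int | None = None

    def __post_init__(self) -> None:
        channels = tuple(frozenset(c) for c in self.channels)
        object.__setattr__(self, "channels", channels)
        if not any(channels):
            raise ValueError("at least one channel must be non-empty")
        seen: set[str] = set()
        for ch in channels:
            if ch & seen:
                raise ValueError(f"channels are not disjoint: {sorted(ch & seen)}")
            seen |= ch
        if self.protease not in _PROTEASES:
            raise ValueError(f"unknown protease: {self.protease!r}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be non-negative")
        if self.max_cycles is not None and self.max_cycles < 1:
            raise ValueError("max_cycles must be positive when set")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_of(self, residue: str) -> int | None:
        for j, ch in enumerate(self.channels):
            if residue in ch:
                return j
        return None

    def to_dict(self) -> dict:
        return {
            "channels": ["".join(sorted(c)) for c in self.channels],
            "protease": self.protease,
            "missed_cleavages": self.missed_cleavages,
            "allow_ambiguous": self.allow_ambiguous,
            "max_cycles": self.max_cycles,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LabelingScheme":
        return cls(
            channels=tuple(frozenset(c) for c in d["channels"]),
            protease=d.get("protease", "trypsin"),
            missed_cleavages=d.get("missed_cleavages", 0),
            allow_ambiguous=d.get("allow_ambiguous", False),
            max_cycles=d.get("max_cycles"),
        )


@dataclass(frozen=True)
class FluorString:
    """Canonical dye pattern of a peptide.

    ``code`` holds one symbol per peptide position: the channel index for a
    labeled residue, ``"."`` for an unlabeled one.  Under a ``max_cycles``
    collapse, dyes past the cycle horizon appear as a sorted digit suffix
    after ``"|"`` (their order is unresolvable without further Edman cycles).
    All peptides without any labelable residue share the single null string,
    encoded as ``code == ""``.
    """

    code: str

    @property
    def n_dyes(self) -> int:
        return sum(c not in (UNLABELED, "|") for c in self.code)

    @property
    def is_null(self) -> bool:
        return self.code == ""

    def per_channel_counts(self, n_channels: int) -> tuple[int, ...]:
        return tuple(self.code.count(str(j)) for j in range(n_channels))


F_NULL = FluorString("")


def _validate_sequence(sequence: str, allow_ambiguous: bool) -> str:
    if not sequence:
        raise ValueError("empty protein sequence")
    seq = sequence.upper()
    allowed = STANDARD_AA | (AMBIGUOUS_AA if allow_ambiguous else set())
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)} in sequence "
                         "(pass allow_ambiguous=True to treat as unlabelable)")
    return seq


def digest(sequence: str, scheme: LabelingScheme) -> list[str]:
    """Cleave a protein into peptides under the scheme's protease rule.

    With trypsin the cut falls C-terminal to K or R unless the next residue
    is P.  With ``missed_cleavages = n`` every run of up to ``n + 1``
    consecutive fragments is also emitted, alongside the complete digest.
    """
    seq = _validate_sequence(sequence, scheme.allow_ambiguous)
    cut_after, block_next = _PROTEASES[scheme.protease]
    fragments: list[str] = []
    start = 0
    for i, aa in enumerate(seq):
        if aa in cut_after and (i + 1 == len(seq) or seq[i + 1] not in block_next):
            fragments.append(seq[start:i + 1])
            start = i + 1
    if start < len(seq):
        fragments.append(seq[start:])
    if scheme.missed_cleavages == 0:
        return fragments
    peptides = []
    for i in range(len(fragments)):
        for j in range(i, min(i + scheme.missed_cleavages + 1, len(fragments))):
            peptides.append("".join(fragments[i:j + 1]))
    return peptides


def label(peptide: str, scheme: LabelingScheme) -> FluorString:
    """Map a peptide to its ideal fluorescence string (one dye per match)."""
    if not peptide:
        raise ValueError("empty peptide")
    symbols = []
    for aa in peptide:
        j = scheme.channel_of(aa)
        symbols.append(UNLABELED if j is None else str(j))
    if scheme.max_cycles is not None and len(symbols) > scheme.max_cycles:
        head = symbols[: scheme.max_cycles]
        tail_dyes = sorted(c for c in symbols[scheme.max_cycles:] if c != UNLABELED)
        code = "".join(head) + ("|" + "".join(tail_dyes) if tail_dyes else "")
    else:
        code = "".join(symbols)
    if all(c == UNLABELED for c in code):
        return F_NULL
    return FluorString(code)


@dataclass
class FluorDictionary:
    """The fluorescence-string domain D_F of a protein database.

    Attributes
    ----------
    strings
        Indexed list of distinct :class:`FluorString` values (sorted by
        ``(len(code), code)`` so rebuilds are bit-stable).
    protein_ids
        Ordered protein identifiers (domain D_Y, size ``n_proteins``).
    counts
        CSR matrix of shape ``(n_proteins, n_strings)``; entry ``(y, f)`` is
        the number of digest peptides of protein *y* whose ideal labeling is
        string *f* (the model's ``c(y, f)``).
    scheme
        The labeling scheme the dictionary was built under.
    """

    strings: list[FluorString]
    protein_ids: list[str]
    counts: sparse.csr_matrix
    scheme: LabelingScheme
    string_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.string_index = {s.code: i for i, s in enumerate(self.strings)}

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_strings(self) -> int:
        return len(self.strings)

    @property
    def null_index(self) -> int | None:
        return self.string_index.get("")

    @property
    def n_observable(self) -> int:
        return self.n_strings - (self.null_index is not None)

    @property
    def n_dyes(self) -> np.ndarray:
        """Vector N_d(f) over string indices."""
        return np.array([s.n_dyes for s in self.strings], dtype=np.int64)

    def strings_of(self, y: int) -> np.ndarray:
        """Indices of non-null strings producible by protein ``y`` (D_F(y))."""
        row = self.counts.getrow(y)
        idx = row.indices
        null = self.null_index
        return idx[idx != null] if null is not None else idx.copy()


def build_dictionary(
    records: Iterable[tuple[str, str]], scheme: LabelingScheme
) -> FluorDictionary:
    """Build the fluorescence-string dictionary for a protein database.

    ``records`` is an iterable of ``(protein_id, sequence)``.  Every digest
    peptide of every protein is assigned to exactly one string; counts
    aggregate identical strings within and across proteins.
    """
    records = list(records)
    if not records:
        raise ValueError("no FASTA records")
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein ids: {dupes}")

    per_protein: list[dict[str, int]] = []
    codes: set[str] = set()
    for pid, seq in records:
        tally: dict[str, int] = {}
        try:
            peptides = digest(seq, scheme)
        except ValueError as exc:
            raise ValueError(f"protein {pid!r}: {exc}") from exc
        for pep in peptides:
            code = label(pep, scheme).code
            tally[code] = tally.get(code, 0) + 1
        per_protein.append(tally)
        codes |= tally.keys()

    strings = sorted((FluorString(c) for c in codes), key=lambda s: (len(s.code), s.code))
    index = {s.code: i for i, s in enumerate(strings)}
    mat = sparse.dok_matrix((len(records), len(strings)), dtype=np.int64)
    for y, tally in enumerate(per_protein):
        for code, n in tally.items():
            mat[y, index[code]] = n
    return FluorDictionary(strings=strings, protein_ids=ids,
                           counts=mat.tocsr(), scheme=scheme)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA; the first whitespace token is the id."""
    path = Path(path)
    try:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    except Exception as exc:  # pragma: no cover - biopython error context
        raise ValueError(f"failed to parse FASTA {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def build_dictionary_from_fasta(path: str | Path, scheme: LabelingScheme) -> FluorDictionary:
    return build_dictionary(read_fasta(path), scheme)


# ---------------------------------------------------------------------------
# serialization: strings.tsv + counts.tsv + scheme.json
# ---------------------------------------------------------------------------

def save_dictionary(d: FluorDictionary, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "strings.tsv", "w") as fh:
        fh.write("string_index\tcode\tn_dyes\n")
        for i, s in enumerate(d.strings):
            fh.write(f"{i}\t{s.code or 'f_null'}\t{s.n_dyes}\n")
    coo = d.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(outdir / "counts.tsv", "w") as fh:
        fh.write("protein_id\tstring_index\tcount\n")
        for k in order:
            fh.write(f"{d.protein_ids[coo.row[k]]}\t{coo.col[k]}\t{coo.data[k]}\n")
    sidecar = {"scheme": d.scheme.to_dict(), "protein_ids": d.protein_ids,
               "n_strings": d.n_strings}
    (outdir / "dictionary.json").write_text(json.dumps(sidecar, indent=2))


def load_dictionary(outdir: str | Path) -> FluorDictionary:
    outdir = Path(outdir)
    sidecar = json.loads((outdir / "dictionary.json").read_text())
    scheme = LabelingScheme.from_dict(sidecar["scheme"])
    protein_ids: Sequence[str] = sidecar["protein_ids"]
    strings: list[FluorString] = []
    with open(outdir / "strings.tsv") as fh:
        next(fh)
        for line in fh:
            _, code, _ = line.rstrip("\n").split("\t")
            strings.append(FluorString("" if code == "f_null" else code))
    pid_index = {p: y for y, p in enumerate(protein_ids)}
    rows, cols, data = [], [], []
    with open(outdir / "counts.tsv") as fh:
        next(fh)
        for line in fh:
            pid, f, n = line.rstrip("\n").split("\t")
            rows.append(pid_index[pid])
            cols.append(int(f))
            data.append(int(n))
    counts = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(protein_ids), len(strings)), dtype=np.int64
    )
    return FluorDictionary(strings=strings, protein_ids=list(protein_ids),
                           counts=counts, scheme=scheme)
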
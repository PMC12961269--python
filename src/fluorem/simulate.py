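"""Synthetic abundance profiles, read sets, and per-read posteriors.

The simulation protocol mirrors how replicate benchmark datasets are built
for fluorosequencing inference studies:

1. a ground-truth abundance profile is drawn by normalizing i.i.d. unit
   exponentials (at proteome scale this yields a dynamic range of roughly
   six decades between the most and least abundant protein);
2. a finite *shared pool* of reads is built per observable fluorescence
   string, and each replicate dataset samples its reads from that pool
   according to the mixture distribution P_Fo implied by the profile;
3. each read is summarized by a sparse classifier posterior over strings —
   either an *oracle* that knows the true string and misassigns with rate
   ``e``, or a synthetic distance-kernel classifier standing in for a real
   peptide classifier.

Posteriors are sparsified to their top-``N_b`` entries; the clipped mass is
spread uniformly over all observable strings as the per-read remainder
``r_k``, so the reconstructed row ``listed + r_k`` is again a distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .model import string_distribution
from .peptidome import FluorDictionary

POSTERIOR_NORM_ATOL = 1e-9


@dataclass
class ReadSet:
    """Ground-truth reads: the observable string behind each read."""

    true_string: np.ndarray  # (n_reads,) int64 string indices, never f_null
    dataset_id: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.true_string = np.asarray(self.true_string, dtype=np.int64)
        if self.true_string.size == 0:
            raise ValueError("a read set must contain at least one read")

    @property
    def n_reads(self) -> int:
        return int(self.true_string.size)


@dataclass
class SparsePosterior:
    """Top-N_b classifier posteriors plus the uniform remainder r_k.

    ``listed`` is an (n_reads, n_strings) CSR matrix holding the retained
    posterior masses; ``remainder`` the per-read r_k.  For every read,
    ``listed.sum() + n_strings * r_k == 1``.
    """

    listed: sparse.csr_matrix
    remainder: np.ndarray
    n_strings: int = field(default=0)

    def __post_init__(self) -> None:
        self.remainder = np.asarray(self.remainder, dtype=np.float64)
        if self.n_strings == 0:
            self.n_strings = self.listed.shape[1]
        if self.listed.shape[0] != self.remainder.shape[0]:
            raise ValueError("remainder length does not match read count")
        if np.any(self.remainder < -POSTERIOR_NORM_ATOL):
            raise ValueError("negative remainder mass")

    @property
    def n_reads(self) -> int:
        return int(self.listed.shape[0])

    def validate(self) -> None:
        """Check the sparsification normalization identity per read."""
        totals = np.asarray(self.listed.sum(axis=1)).ravel() \
            + self.n_strings * self.remainder
        if not np.allclose(totals, 1.0, atol=POSTERIOR_NORM_ATOL, rtol=0):
            k = int(np.argmax(np.abs(totals - 1.0)))
            raise ValueError(f"posterior row {k} sums to {totals[k]:.12g}")

    def dense(self) -> np.ndarray:
        """Reconstructed dense posterior rows (listed mass + r_k baseline)."""
        return self.listed.toarray() + self.remainder[:, None]


def sample_abundances(n_proteins: int, rng: np.random.Generator | int) -> np.ndarray:
    """Ground-truth profile: normalized i.i.d. unit exponentials."""
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    rng = np.random.default_rng(rng)
    x = rng.exponential(scale=1.0, size=n_proteins)
    return x / x.sum()


class ReadPool:
    """A finite shared pool of reads per observable fluorescence string.

    Replicate datasets drawing from the same pool reuse the same underlying
    simulated reads (slots); here a read is fully summarized by its true
    string, so slots carry only an identity, sampled uniformly with
    replacement.
    """

    def __init__(self, n_strings: int, pool_per_string: int, seed: int | None = None):
        if pool_per_string < 1:
            raise ValueError("pool_per_string must be positive")
        self.n_strings = n_strings
        self.pool_per_string = pool_per_string
        self.seed = seed

    def draw_slots(self, strings: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return rng.integers(0, self.pool_per_string, size=strings.shape[0])


def simulate_reads(
    p: np.ndarray,
    d: FluorDictionary,
    m: float,
    n_reads: int,
    rng: np.random.Generator | int,
    pool: ReadPool | None = None,
    pool_per_string: int | None = None,
    dataset_id: int = 0,
) -> ReadSet:
    """Draw reads i.i.d. from the observable-string mixture P_Fo.

    When a pool (or ``pool_per_string``) is given, each draw is routed
    through the finite per-string read pool; the marginal string law is
    unchanged because pool slots are exchangeable.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(rng)
    pfo = string_distribution(p, d, m)
    pfo = pfo / pfo.sum()  # suppress float drift for the sampler
    strings = rng.choice(pfo.shape[0], size=n_reads, p=pfo)
    if pool is None and pool_per_string is not None:
        pool = ReadPool(d.n_strings, pool_per_string)
    if pool is not None:
        pool.draw_slots(strings, rng)  # pool routing; slots are exchangeable
    return ReadSet(true_string=strings.astype(np.int64), dataset_id=dataset_id)


def sparsify(dense_rows: np.ndarray, n_b: int, n_strings: int | None = None) -> SparsePosterior:
    """Keep the top-``n_b`` entries of each posterior row.

    Ties are broken by ascending string index (deterministic).  The clipped
    mass of row ``k`` is spread uniformly: ``r_k = (1 - kept) / n_strings``.
    """
    dense_rows = np.atleast_2d(np.asarray(dense_rows, dtype=np.float64))
    n_reads, n_cols = dense_rows.shape
    if n_strings is None:
        n_strings = n_cols
    if not 1 <= n_b <= n_strings:
        raise ValueError("n_b must be in [1, n_strings]")
    n_keep = min(n_b, n_cols)
    # stable argsort on -p: ties fall back to ascending column index
    order = np.argsort(-dense_rows, axis=1, kind="stable")[:, :n_keep]
    kept = np.take_along_axis(dense_rows, order, axis=1)
    r = (1.0 - kept.sum(axis=1)) / n_strings
    r = np.maximum(r, 0.0)  # clip float dust
    rows = np.repeat(np.arange(n_reads), n_keep)
    listed = sparse.csr_matrix(
        (kept.ravel(), (rows, order.ravel())), shape=(n_reads, n_cols)
    )
    listed.eliminate_zeros()  # listed masses must be strictly positive
    return SparsePosterior(listed=listed, remainder=r, n_strings=n_strings)


def _expand_per_string(
    reads: ReadSet, template: SparsePosterior, string_of_row: np.ndarray
) -> SparsePosterior:
    """Broadcast per-unique-string posterior rows to per-read rows."""
    lookup = {int(s): i for i, s in enumerate(string_of_row)}
    row_of_read = np.array([lookup[int(s)] for s in reads.true_string])
    listed = template.listed[row_of_read]
    return SparsePosterior(listed=listed.tocsr(),
                           remainder=template.remainder[row_of_read],
                           n_strings=template.n_strings)


def oracle_posterior(
    reads: ReadSet, e: float, n_strings: int, n_b: int,
    null_index: int | None = None,
) -> SparsePosterior:
    """Oracle classifier: mass ``1 - e`` on the true string, ``e`` uniform.

    The dense oracle row ``(1-e) δ_true + e/|D_F|`` is formed per read and
    sparsified to its top-``n_b`` entries.  With ``e = 0`` the posterior is a
    point mass and ``r_k = 0``.  ``|D_F|`` counts observable strings: when
    ``null_index`` names an f_null column it receives no mass and is excluded
    from the count.
    """
    if not 0.0 <= e <= 1.0:
        raise ValueError("oracle error rate e must be in [0, 1]")
    n_obs = n_strings - (null_index is not None)
    n_b = min(n_b, n_obs)
    uniq = np.unique(reads.true_string)
    dense = np.full((uniq.size, n_strings), e / n_obs)
    if null_index is not None:
        dense[:, null_index] = 0.0
    dense[np.arange(uniq.size), uniq] += 1.0 - e
    template = sparsify(dense, n_b, n_obs)
    return _expand_per_string(reads, template, uniq)


def dye_count_distance(d: FluorDictionary) -> np.ndarray:
    """Pairwise per-channel dye-count L1 distance between strings.

    Ignores dye positions; two strings with identical per-channel dye counts
    are at distance 0 even if the positions differ, so this distance does
    not separate all distinct strings.
    """
    n_ch = d.scheme.n_channels
    counts = np.array(
        [s.per_channel_counts(n_ch) for s in d.strings], dtype=np.float64
    )
    return np.abs(counts[:, None, :] - counts[None, :, :]).sum(axis=2)


def positional_mismatch_distance(d: FluorDictionary) -> np.ndarray:
    """Pairwise padded-Hamming-plus-length distance between dye codes.

    Codes are right-padded with the unlabeled marker to a common length;
    the distance is the count of mismatching positions plus the absolute
    peptide-length difference.  Zero iff the strings are identical, so a
    distance-kernel classifier concentrates on the true string in the
    sharp-kernel limit.
    """
    codes = [s.code for s in d.strings]
    width = max(len(c) for c in codes)
    arr = np.array([list(c.ljust(width, ".")) for c in codes])
    mismatches = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    lengths = np.array([len(c) for c in codes])
    return (mismatches + np.abs(lengths[:, None] - lengths[None, :])).astype(np.float64)


def noisy_posterior(
    reads: ReadSet,
    d: FluorDictionary,
    kernel_decay: float,
    n_b: int,
    distance: np.ndarray | None = None,
) -> SparsePosterior:
    """Synthetic classifier: posterior ∝ exp(-decay * distance to truth).

    A stand-in for a real peptide classifier: confusion decays with the
    dye-pattern distance between strings (positional mismatch count by
    default).  Mass is supported on observable strings only.  As
    ``kernel_decay → ∞`` this degenerates to the perfect oracle.
    """
    if kernel_decay < 0:
        raise ValueError("kernel_decay must be non-negative")
    if distance is None:
        distance = positional_mismatch_distance(d)
    observable = d.n_dyes > 0
    uniq = np.unique(reads.true_string)
    logits = -kernel_decay * distance[uniq][:, :]
    logits[:, ~observable] = -np.inf
    logits -= logits.max(axis=1, keepdims=True)
    dense = np.exp(logits)
    dense /= dense.sum(axis=1, keepdims=True)
    n_b = min(n_b, d.n_observable)
    template = sparsify(dense, n_b, d.n_observable)
    return _expand_per_string(reads, template, uniq)


# ---------------------------------------------------------------------------
# serialization: reads TSV; posterior coordinate TSV + r_k sidecar
# ---------------------------------------------------------------------------

def save_reads(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttrue_string_index\tdataset_id\n")
        for k, s in enumerate(reads.true_string):
            fh.write(f"{k}\t{s}\t{reads.dataset_id}\n")


def load_reads(path: str | Path) -> ReadSet:
    data = np.loadtxt(path, skiprows=1, dtype=np.int64, ndmin=2)
    return ReadSet(true_string=data[:, 1], dataset_id=int(data[0, 2]))


def save_posterior(post: SparsePosterior, prefix: str | Path) -> None:
    """Write ``<prefix>.posterior.tsv`` (coo) and ``<prefix>.remainder.tsv``."""
    prefix = Path(prefix)
    coo = post.listed.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(f"{prefix}.posterior.tsv", "w") as fh:
        fh.write("read_id\tstring_index\tprobability\n")
        for k in order:
            fh.write(f"{coo.row[k]}\t{coo.col[k]}\t{coo.data[k]:.17g}\n")
    with open(f"{prefix}.remainder.tsv", "w") as fh:
        fh.write("read_id\tr_k\n")
        for k, r in enumerate(post.remainder):
            fh.write(f"{k}\t{r:.17g}\n")
    meta = {"n_reads": post.n_reads, "n_strings": post.n_strings,
            "n_columns": post.listed.shape[1]}
    Path(f"{prefix}.posterior.json").write_text(json.dumps(meta))


def load_posterior(prefix: str | Path) -> SparsePosterior:
    prefix = Path(prefix)
    meta = json.loads(Path(f"{prefix}.posterior.json").read_text())
    coo = np.loadtxt(f"{prefix}.posterior.tsv", skiprows=1, ndmin=2)
    r = np.loadtxt(f"{prefix}.remainder.tsv", skiprows=1, ndmin=2)[:, 1]
    listed = sparse.csr_matrix(
        (coo[:, 2], (coo[:, 0].astype(int), coo[:, 1].astype(int))),
        shape=(meta["n_reads"], meta.get("n_columns", meta["n_strings"])),
    )
    return SparsePosterior(listed=listed, remainder=r, n_strings=meta["n_strings"])
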
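"""Distribution transforms linking proteins, indicators, and dye patterns.

Three distributions describe one experiment:

* ``p`` — relative protein abundances (the quantity to be estimated),
* ``q`` — the *protein indicator* distribution: the probability that a
  uniformly drawn observable read originated from each protein,
* ``P_Fo`` — the distribution of observable fluorescence strings.

They are connected through the dye miss rate ``m`` (an ideally labeled
residue fails to carry a dye with probability ``m``, so a peptide with
``N_d`` ideal labels is completely dark with probability ``m**N_d``) and the
expected observable-peptide count per protein molecule::

    E_Fo(y) = sum over digest peptides of y of (1 - m**N_d(peptide))

    q_y  ∝  E_Fo(y) * p_y                       (indicator transform)
    P_Fo(f|y) = c(y,f) * (1 - m**N_d(f)) / E_Fo(y)   (string conditional)
    P_Fo(f)  = sum_y P_Fo(f|y) * q_y            (read-string mixture)

Proteins whose every peptide is unlabelable have ``E_Fo(y) = 0``; they
produce no reads and are excluded from inference (their estimated abundance
is reported as zero and flagged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .peptidome import FluorDictionary

SIMPLEX_ATOL = 1e-9


@dataclass(frozen=True)
class ErrorModel:
    """Scalar error parameters: dye miss rate ``m`` and oracle error ``e``."""

    m: float = 0.0
    e: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.m < 1.0:
            raise ValueError("dye miss rate m must be in [0, 1)")
        if not 0.0 <= self.e <= 1.0:
            raise ValueError("oracle error rate e must be in [0, 1]")


def check_simplex(v: np.ndarray, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.any(v < 0):
        raise ValueError(f"{name} has negative entries")
    if abs(v.sum() - 1.0) > SIMPLEX_ATOL:
        raise ValueError(f"{name} does not sum to 1 (sum={v.sum():.12g})")
    return v


def _normalize(w: np.ndarray, err: str) -> np.ndarray:
    total = w.sum()
    if total <= 0:
        raise ValueError(err)
    return w / total


def observability_weights(d: FluorDictionary, m: float) -> np.ndarray:
    """Per-string observation probability ``1 - m**N_d(f)`` (0 for f_null)."""
    nd = d.n_dyes
    w = -np.expm1(nd * np.log(m)) if m > 0 else (nd > 0).astype(np.float64)
    w = np.where(nd == 0, 0.0, w)
    return w


def observable_transform(pf: np.ndarray, d: FluorDictionary, m: float) -> np.ndarray:
    """Condition a fluorescence-string distribution on being observed.

    Given ``P_F`` over all dictionary strings, returns
    ``P_Fo(f) = K (1 - m**N_d(f)) P_F(f)`` with ``P_Fo(f_null) = 0``.
    """
    pf = check_simplex(pf, "P_F")
    if pf.shape[0] != d.n_strings:
        raise ValueError("P_F length does not match dictionary")
    w = observability_weights(d, m) * pf
    return _normalize(w, "no observable mass (all weight on dark strings)")


def expected_observable_strings(d: FluorDictionary, m: float) -> np.ndarray:
    """E_Fo(y): expected observable peptide molecules per molecule of y."""
    w = observability_weights(d, m)
    return np.asarray(d.counts @ w, dtype=np.float64).ravel()


def abundance_to_indicator(p: np.ndarray, efo: np.ndarray) -> np.ndarray:
    """q_y ∝ E_Fo(y) * p_y (the forward indicator transform)."""
    p = check_simplex(p, "abundance p")
    return _normalize(efo * p, "no observable protein mass")


def indicator_to_abundance(q: np.ndarray, efo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Invert the indicator transform: p_y ∝ q_y / E_Fo(y).

    Returns ``(p, unobservable_mask)``.  Proteins with ``E_Fo(y) = 0``
    receive abundance 0 and are flagged True in the mask; indicator mass on
    such a protein is an error.
    """
    q = check_simplex(q, "indicator q")
    efo = np.asarray(efo, dtype=np.float64)
    unobservable = efo == 0
    if np.any(q[unobservable] > 0):
        bad = int(np.flatnonzero(unobservable & (q > 0))[0])
        raise ValueError(f"indicator mass on unobservable protein (index {bad})")
    p = np.zeros_like(q)
    p[~unobservable] = q[~unobservable] / efo[~unobservable]
    return _normalize(p, "no observable protein mass"), unobservable


def string_conditional(d: FluorDictionary, m: float) -> sparse.csr_matrix:
    """Sparse conditional table P_Fo|I(f|y), shape (n_proteins, n_strings).

    Row ``y`` is ``c(y,f) (1 - m**N_d(f)) / E_Fo(y)`` over the observable
    strings of protein ``y``; rows of unobservable proteins are empty.
    """
    w = observability_weights(d, m)
    weighted = d.counts.multiply(w).tocsr()
    efo = np.asarray(weighted.sum(axis=1)).ravel()
    inv = np.divide(1.0, efo, out=np.zeros_like(efo), where=efo > 0)
    cond = sparse.diags(inv) @ weighted
    cond.eliminate_zeros()
    return cond.tocsr()


def string_distribution(p: np.ndarray, d: FluorDictionary, m: float) -> np.ndarray:
    """P_Fo(f) = Σ_y P_Fo|I(f|y) q_y — the read-generating distribution."""
    efo = expected_observable_strings(d, m)
    q = abundance_to_indicator(p, efo)
    cond = string_conditional(d, m)
    return np.asarray(q @ cond).ravel()
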
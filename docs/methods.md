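# Methods

## Generative model

A fluorosequencing experiment over a database of `N_P` proteins is modeled
in three layers.

**Peptidome.** Each protein is digested in silico (trypsin: cleave
C-terminal to K/R unless the next residue is P; `missed_cleavages`
fragments may be rejoined) and each peptide is mapped to its *fluorescence
string*: the positional pattern of dye channels over its residues, with
every dye-free peptide collapsed into the single null string `f_null`. The
dictionary records `c(y, f)`, the number of digest peptides of protein `y`
with string `f`. The canonical string encoding is the full positional
dye sequence — the strictest equivalence. An optional `max_cycles` collapse
pools dye positions beyond a cycle horizon into unordered per-channel
counts, for users emulating instruments that run a fixed number of Edman
cycles; position information past the horizon is physically unresolvable
there.

**Observation.** Each ideally labeled residue independently fails to carry
a dye with miss rate `m ∈ [0, 1)`, so a peptide with `N_d` ideal labels is
completely dark — unobservable — with probability `m^N_d`. This single
parameter is the only peptide-loss mechanism modeled at this layer;
attachment-efficiency differences between residues, surface losses, Edman
failure and dye bleaching are deliberately out of scope (real classifiers
absorb them into their posteriors). The central modeling commitment is
reading the expected observable yield of protein `y` as the expected count
of observable peptide molecules per protein molecule,

    E_Fo(y) = Σ_pep (1 − m^{N_d(pep)}),

which is the unique reading consistent with the per-peptide miss model; the
per-protein string conditional `P_Fo|I(f|y) = c(y,f)(1 − m^{N_d(f)})/E_Fo(y)`
follows by normalization and is verified against a Monte-Carlo
dye-attachment oracle in the tests. Proteins with `E_Fo(y) = 0` produce no
reads; they are excluded from inference, estimated at zero, and flagged.

**Reads.** A read's hidden state is its observable fluorescence string,
drawn from the mixture `P_Fo(f) = Σ_y P_Fo|I(f|y) q_y` with
`q_y ∝ E_Fo(y) p_y`. Raw per-cycle intensity matrices are never
materialized: the EM consumes only classifier posteriors, so a simulated
read is its true string plus a posterior row.

## Posterior sources and sparsification

Two built-in posterior sources bracket real classifiers:

* **Oracle** — probability `1 − e` on the true string, `e` spread uniformly
  over observable strings. `e = 0` is a perfect classifier and upper-bounds
  achievable accuracy; `e` near 1 is uninformative.
* **Distance kernel** — mass `∝ exp(−decay · d(f, f_true))` over observable
  strings, a synthetic stand-in with graded, structured confusion. The
  default distance is the positional mismatch count between padded dye
  codes plus the absolute length difference. A per-channel dye-count L1
  distance is also provided (`dye_count_distance`), but it is not definite:
  distinct strings sharing channel counts sit at distance zero, so the
  sharp-kernel limit would not concentrate on the true string; the default
  therefore uses the positional distance, which is zero iff the strings are
  identical.

Every posterior row is reduced to its `N_b` largest entries (ties broken by
ascending string index, deterministically); the clipped mass is spread
uniformly, `r_k = (1 − Σ_{f∈G_k} P̂(f|x_k)) / |D_F|`. The convention here is
that `|D_F|` counts **observable** strings only, since posteriors carry no
mass on `f_null`; at realistic dictionary sizes the one-count difference is
immaterial, but it is fixed and declared. With `N_b = |D_F|` the remainder
is exactly zero and sparsification is lossless.

## EM

The kernel `η_{y,k} = r_k + Σ_{f ∈ D_F(y)∩G_k} P̂(f|x_k) P_Fo|I(f|y)` is
assembled once as a sparse matrix product (posteriors × conditionalᵀ) plus
the shared additive baseline `r_k`; it is never renormalized per row, which
would break the additive remainder structure. Each epoch computes
responsibilities `γ_{y,k} ∝ η_{y,k} q_y` and averages them over reads.
The surrogate objective `Σ_k log Σ_y η_{y,k} q_y` equals the data
log-likelihood up to per-read additive constants (the classifier's
normalizers cancel); its differences between estimates are exact likelihood
differences, and it is non-decreasing across epochs — asserted in tests
with `1e-8` absolute slack for float accumulation.

Numerical choices: per-read denominators are floored at `1e-300` (an
exactly zero mixture mass raises an error naming the read); probability
vectors are validated to sum to 1 within `1e-9` and renormalized on
construction to suppress drift; the indicator↔abundance round trip is exact
to machine precision on its valid domain.

Defaults: uniform initialization over observable proteins (a warm start is
supported so the EM can refine an external estimate) and 30 epochs.
Stopping options: fixed epochs (default); a relative surrogate-likelihood
tolerance (`1e-8`); or `oracle-mae`, which returns the MAE-minimizing epoch
and is usable only in simulation — the MAE trace requires the ground
truth, so results produced with it are flagged. MAE need not fall
monotonically (EM guarantees likelihood ascent, not external-metric
descent), and nothing in the package asserts that it does.

## Synthetic data and what the benchmarks show

The replicate-study generator emulates the standard simulation protocol:

* **Abundance profiles** are normalized i.i.d. unit exponentials (the rate
  is irrelevant after normalization). At proteome scale (`N_P ≈ 20 000`)
  this yields a max/min dynamic range near six decades, matching the order
  statistics of exponentials.
* **Replicates**: ten datasets per study, each with its own profile, drawn
  from a **shared pool** of reads per fluorescence string — 1000 slots per
  string for the five-protein benchmark. Slots are sampled uniformly with
  replacement (so any read count is supported); since a simulated read is
  fully summarized by its string, pool routing changes shared-read
  bookkeeping, not the marginal string law.
* **Study conditions** for the headline five-protein benchmark: five
  synthetic 200-residue proteins (random sequences with a
  composition-weighted alphabet; the channels label D/E, C and Y), dye miss
  rate `m = 0.1`, oracle error `e = 0.05` as the low-error posterior
  source, `N_b = 40`, `10^6` reads per dataset, 30 epochs.

The generator does **not** simulate per-cycle intensities, Edman failure,
dye loss, blocking, or any classifier's specific error structure; the
oracle and kernel posteriors are idealized. Passing benchmarks therefore
demonstrate that the inference machinery is correct and well-conditioned
under the declared error model — not that a particular real classifier
will reach the same accuracy on instrument data. Proteome-scale runs
(`~2 × 10^4` proteins, `10^7` reads) are supported by the same code paths
but are exercised here only through invariant suites at small scale; the
test and benchmark sizes (up to `10^6` reads, five proteins) were chosen as
the package's desk-scale reference conditions.

## Design notes

* "Protein" means one FASTA record (gene-level bookkeeping); isoforms,
  PTMs, and probabilistic labeling at dictionary-build time are out of
  scope. N-terminal methionine is not stripped. Non-standard residues
  (B/Z/X/U) are rejected by default or treated as unlabelable with
  `allow_ambiguous`.
* String indices are assigned by sorting canonical codes, so rebuilding
  from identical inputs yields a bit-identical dictionary; `f_null`, when
  present, is always index 0.
* All on-disk formats are plain text (TSV/CSV/JSON): dictionary tables,
  read sets, sparse posterior coordinates with a per-read remainder
  sidecar — the latter doubling as the import format for external
  classifier posteriors. Every CLI output directory carries a
  `manifest.json` with the parameters and seeds needed to re-run it.
* Complexity per epoch is `O(nnz(η))`, i.e. proportional to
  `Σ_k |G_k ∩ D_F(·)|`; memory is the sparse kernel plus the trace.

## Known limitations

Identifiability is limited by the dictionary: proteins with identical
observable string profiles are interchangeable to the likelihood (any
split of their mass is a fixed point), and EM finds local optima of a
non-convex surface — multi-start ranking is not implemented. High
classifier error at scale can make the MAE rise with epochs even as the
likelihood climbs; the simulation-only `oracle-mae` stop exists to study
that regime, and calibrating a fixed stopping epoch from simulations is the
pragmatic recourse on real data.
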
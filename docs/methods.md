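# Methods

## Scope and model

`raseff` reconstructs, from structures and curated alignments, the
residue-level anatomy of GTPase-effector binding interfaces, and fits
equilibrium affinities from fluorescence-polarization (FP) titrations.
The pipeline has four analytic stages and a synthetic-data layer that
supplies ground-truth inputs for all of them.

### Contacts

Two residues — one on the GTPase chain, one on the effector chain — are
"in contact" when the minimum distance over all heavy-atom pairs is at
most a cutoff, default **4.0 Å**. This is the standard heavy-atom
convention: crystal structures mostly lack hydrogens, so hydrogens (and
deuteriums) are excluded from the distance computation. Waters, ions
and other non-polymer heteroatoms never participate; the matrix relates
amino acids only. For alternate conformations the highest-occupancy
altloc of each atom is kept, ties broken by altloc identifier order
(deterministic and conventional). Residues left without heavy atoms are
skipped with a logged warning rather than failing the complex, to
tolerate sparse crystallographic models. Multi-model files use the
manifest's `model_index` (default 0).

Extraction uses a KD-tree over one chain's atoms queried with the
other's; the test suite holds it to exact agreement with an independent
all-atom-pair scan.

### Alignment mapping and reference numbering

Structure chains are tied to alignment rows by **pairwise global
alignment** of the chain-derived one-letter sequence against the
ungapped row (match +1, mismatch −1, gap open −5, extend −0.5, terminal
gaps free), composed with the row's gap pattern. Author residue
numbering in coordinate files is never used for mapping — it is
unreliable across depositions; it survives only as the residue identity
in reports. A chain must reach 80% identity to its assigned row over
the aligned span, guarding against wrong-row assignment. Residues the
pairwise step aligns to gaps are reported as unmapped, not silently
dropped.

Matrix axes carry **reference numbering**: the k-th non-gap column of
the designated reference row (HRAS for the GTPase side; CRAF or RASSF5
for the effector side) is labeled `<aa><start + k − 1>`, e.g. `E37`.
Columns gapped in the reference become insertion labels (`ins31a`)
anchored to the preceding number, so contacts falling in
effector-specific insertions are retained rather than discarded.

### Conservation

A column is **conserved** when at least a threshold fraction (default
0.9) of its non-gap residues fall into one similarity group of a
reduced alphabet: {D,E}, {K,R}, {N,Q}, {S,T}, {I,V,L,M}, {F,Y,W},
{A,G}, {C}, {H}, {P}. The groups mirror the slash notation commonly
used for interface positions (D/E, R/K, I/V, S/T, Q/N); both the groups
and the threshold are parameters, since no single conservation rule is
canonical. All-gap columns are variable.

### Interaction matrix and hotspots

Each cell counts the number of complexes in which that residue pair is
in contact, so values range from 0 to `n_complexes`. The count is
**binarized per complex**: however many atom pairs qualify, one complex
adds at most 1 to a cell. Every crystallographically independent copy
of a complex in one file counts as its own complex (its own manifest
entry), matching the practice of treating 19 interface copies from 13
entries as 19 complexes.

A residue hotspot on either axis has support = the number of distinct
complexes in which that residue touches the partner chain at all (a
residue contacting three partner residues within one complex has
support 1). The default hotspot threshold is a majority of complexes,
⌈n/2⌉, exposed as `--min-support`; no single published threshold
exists, and the majority reading makes "present in most interfaces"
precise.

### Variant design

A residue-swap proposal transplants the donor row's residues onto the
acceptor at the designated hotspot columns: one substitution per column
where the rows differ and neither carries a gap; gap columns are
reported unswappable (a point substitution cannot express them).
Positions are acceptor-construct coordinates — the count of non-gap
acceptor residues up to the column plus a per-construct
`numbering_offset` — because such variants are conventionally named in
construct-local frames (`A186K/Y187D/V190K/T191H` vs
`V40D/G42I/L43K/K45L/R46H`). Duplicate positions are rejected outright;
a published mutation string that repeats a position with two different
wild-type residues is a recording error, not a design the code should
reproduce. Applying a proposal and re-proposing yields the empty set
(idempotence), which the tests enforce.

### Quadratic (ligand-depletion) Kd fitting

FP titrations hold the labeled GTPase at total concentration R
(default 1 μM) and titrate the effector over L = 0.002–300 μM. Because
R is comparable to many Kd values of interest, the free-ligand
hyperbola is biased and the exact 1:1 isotherm is required. The bound
fraction is the physical root of `R·fb² − (R+L+Kd)·fb + L = 0`:

    fb = ((R + L + Kd) − sqrt((R + L + Kd)² − 4RL)) / (2R)

computed in the algebraically equivalent form `2L / (S + sqrt(S² −
4RL))` to avoid cancellation at L ≪ Kd. The signal is linear in fb:
`P = P_free + (P_bound − P_free)·fb`.

Fitting is trust-region-reflective least squares over (Kd, P_free,
P_bound), Kd bounded positive. Initial Kd is the concentration nearest
half dynamic range; P_free/P_bound start at the first/last deciles.
On non-convergence the fit restarts from five log-spaced Kd values
spanning the titration range. Standard errors come from the covariance
of the fit. Series with zero dynamic range, non-converged fits, and
fits with Kd > 500 μM are reported as `no_binding`.

**Affinity bands.** Kd values classify as high (0.1–5 μM),
intermediate (6–30 μM), low (31–90 μM), very low (91–510 μM),
no binding (> 500 μM). The printed band ranges leave gaps (5–6, 30–31,
90–91); the implementation uses half-open intervals split at the gap
midpoints 5.5 / 30.5 / 90.5 so every positive Kd classifies
deterministically. The benchmark values 0.3, 27 and 65 μM are far from
all boundaries and unaffected by this choice.

**Fit comparison.** Fold change is Kd_A/Kd_B; significance is a
two-sided z-test on the log-Kd difference with delta-method standard
errors (se_log = se_Kd/Kd) propagated from the fits. This reconstructs
"error bars derived from the fitting errors" when no replicates exist;
it is an error-propagation approximation and is labeled as such in the
API. It does not claim to reproduce any particular published p-value,
whose derivation procedure is not specified.

## Synthetic data: what it emulates and what it does not

The generators exist so every stage is testable against planted truth
without downloads or instruments.

**Toy complexes.** Each residue is a rigid planar five-atom fragment
(N, CA, C, O, CB; radius < 2.5 Å, written as ALA). GTPase fragments
occupy a 16 Å 2-D lattice in the z = 0 plane; effector fragments sit on
a parallel lattice 300 Å away. A planted contact (i, j, d) translates
effector fragment j directly above GTPase fragment i at height d, so
the CA–CA pair realizes the minimum heavy-atom distance exactly d
(to the 0.001 Å precision of coordinate records) while every
non-planted intermolecular residue pair stays > 11 Å — far beyond
cutoff + 2 Å. The 16 Å spacing is what guarantees that margin given the
fragment radius. One geometric feasibility rule follows from fragments
occupying single locations: an effector residue can realize at most one
planted contact; violating requests fail explicitly. No physical
realism (folds, rotamers, nucleotides) is attempted — the contact
definition needs only geometry, and passing tests therefore certify
contact topology and counting, not the handling of real crystallographic
pathologies beyond those modeled (altlocs, waters, missing atoms).

**Ensembles.** Core contacts are planted in every complex; residues
unused by the core are paired one-to-one into peripheral candidates,
each planted independently per complex with probability
`peripheral_rate` (the pairing keeps any subset geometrically
realizable). The generator records exactly what it planted, and that
bookkeeping — not the structures — is the oracle the matrix stage is
tested against.

**Alignments.** Conserved columns draw all rows from one similarity
group; variable columns split rows about half-and-half between two
distinct groups, keeping every group below any threshold ≥ 0.6
regardless of row count. Gap-free by construction.

**Titrations.** Signals are the closed-form model plus i.i.d. Gaussian
noise on the polarization readout — the standard noise model for FP
when none is otherwise specified. Defaults: R = 1 μM, 20 log-spaced
concentrations over 0.002–300 μM, P_free = 60, P_bound = 160
(a 100-unit dynamic range typical of mP readouts), noise SD 2.0 = 2% of
the dynamic range, consistent with the scatter of published FP curves.
Replicate count for recovery benchmarks is 100, a free choice balancing
the stability of the median against runtime.

## Numerical and design choices

- Discriminants are clipped at zero before the square root (they are
  analytically non-negative; round-off can undershoot).
- `fraction_bound` is exact at the edge cases L = 0 (0) and Kd = 0,
  L ≥ R (1), and reduces to the hyperbola L/(L+Kd) as R → 0 (tested at
  R = 10⁻⁶·Kd to 10⁻⁴ relative).
- Hotspot and cell reports sort by support/value descending, then
  label, so outputs are deterministic; matrix construction iterates
  complexes in sorted id order and is invariant to ingestion order.
- The matrix pipeline removes partial outputs on failure and names the
  offending complex; reruns on identical inputs are byte-identical.
- Benchmark problem sizes: 200 random complexes of ≤ 60 residues per
  chain for contact-oracle equivalence; 100 replicates per Kd for
  recovery. These keep the full suite in the tens of seconds while
  leaving medians stable to well under the 10% recovery tolerance.

## Known limitations

- The alignment-to-structure mapping is purely sequence-based; a
  hand-curated structural synchronization of alignments can place
  spatially equivalent but sequence-divergent residues in columns this
  procedure will not reproduce exactly.
- The merged effector axis assumes the RA and RB alignments have been
  combined upstream into one alignment with a common reference; the
  pipeline consumes one effector alignment per run (run per family and
  compare otherwise).
- The z-test on log-Kd understates uncertainty when fitting errors are
  themselves poorly determined (few points, weak saturation); with
  replicate data a replicate-based test should replace it.
- Bands are a reporting convention, not a statistical classification;
  Kd values near band edges are sensitive to noise at the few-percent
  level.
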
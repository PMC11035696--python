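# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `molcraft` the way a maintainer would want them written down.
It states no empirical numbers beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## The interactome and its curation

The central data structure is a bipartite graph between ligand nodes
(canonical SMILES) and target nodes (identifiers), with edges carrying
binding affinities on the pActivity scale, pActivity = −log₁₀(affinity in
molar); 1 µM ⇔ 6.0, 200 nM ⇔ ≈ 6.70. Curation rules:

- **Washing**: parse → keep the fragment with the most heavy atoms (salt and
  solvent removal) → neutralize charged atoms where valence permits
  (quaternary nitrogens stay charged; the molecule is kept) → reject
  radicals, molecules with < 3 or > 100 heavy atoms, and unparseable input.
  Rejections are data (reason codes), not exceptions, so batch curation
  continues.
- **Length filter**: a molecule passes if the longest of five seeded
  randomized SMILES renderings is ≤ 97 characters. This bounds decoder
  sequence length for any atom ordering, not just the canonical one.
- **Cutoff**: edges require affinity ≤ 200 nM, boundary inclusive (an
  affinity of exactly 200 nM is kept).
- **Duplicates**: multiple measurements of one (ligand, target) pair are
  aggregated as the *median* pActivity before the cutoff is applied. The
  median is robust to a single discordant assay; this choice is
  configurable in the sense that callers can pre-aggregate differently.
  Mixed affinity types (Ki/IC50/Kd/EC50) are pooled onto the single
  pActivity scale.
- **Minimum ligands**: targets with fewer than five ligands are removed,
  together with ligand nodes this leaves isolated. One pass suffices
  (removing isolated ligands cannot change any target's degree).
- **Allosteric splitting**: a target with both allosteric and orthosteric
  ligands becomes two nodes (`id::allosteric`, `id::orthosteric`); the edge
  multiset and ligand set are conserved.
- **Structural mode**: targets are additionally restricted to those with at
  least one usable structure (ligand MW within 100–1200 g·mol⁻¹, affinity
  ≤ 10 µM).

Training pairs connect molecules through shared targets: in ligand mode all
ordered pairs (Lᵢ, Lⱼ), i ≠ j, of a target's ligands (n(n−1) per target);
in structure mode one (pocket, ligand) pair per edge.

## Graph featurization

**Ligands (2D)**: one node per heavy atom (explicit hydrogens optional via a
flag, off by default — SMILES-derived graphs customarily use heavy atoms
even though H is part of the 10-element vocabulary), features (atom type ∈
{H, C, N, O, F, P, S, Cl, Br, I}, ring flag, aromatic flag, hybridization ∈
{sp³, sp², sp, s}), covalent-bond edges. Elements outside the vocabulary
are a hard error naming the element — silently mapping them would corrupt
the embedding semantics.

**Pockets (3D)**: the pocket is every protein atom whose minimum distance to
any ligand atom is ≤ 5 Å (inclusive). Node features: an element index over
a frozen 22-slot vocabulary (common organic/cofactor elements + reserved
"other"), a (residue, atom-name) index over a frozen 225-slot vocabulary
(the 167 standard heavy-atom names of the 20 amino acids + terminal OXT +
reserved slots, "other" last), the annotated distance to the closest ligand
atom, and the B factor read from the PDB column (the B-factor source is a
pluggable provider; a computed-flexibility provider can be substituted).
Edges connect all atom pairs within 4 Å (inclusive) and carry Fourier
features of the inter-atomic distance: ω_k = kπ/d_cut with d_cut = 4 Å and
n_freq = 8 frequencies by default, giving [sin(ω_k d), cos(ω_k d)]…, a
16-vector. The ladder makes the first harmonic complete half a period at
the edge-radius cutoff; the feature map is smooth in d and purely
distance-based, so pocket graphs are exactly invariant under rigid rotation
and translation — the invariance tests assert this at 1e-9 (features) and
1e-6 (encoder latents).

## Generator

**Encoder.** Node features are embedded (per-feature tables, concatenated,
then a two-layer MLP with tanh) to h⁰. Three message-passing layers update
h^{l+1}_i = φ([h^l_i, Σ_{j∈N(i)} ψ([h^l_i, h^l_j, r_ij])]) where ψ and φ
are two-layer MLPs and r_ij (3D only) is the Fourier edge feature; the sum
over neighbours is the permutation-invariant aggregator. The per-layer
states [h¹, h², h³] are concatenated and projected to final atomic features
H_i. Pooling is attention over learnable seed vectors: scores
H·S^T/√d, softmax per graph, one weighted sum per seed, concatenated
(a light stand-in for a graph multiset transformer; sum pooling is
available behind `pooling="sum"`). Two MLPs map the pooled vector to the
latents l¹ and l² (tanh-bounded, since they initialize LSTM hidden states).

**Conditioning.** In conditioned mode the six wishlist properties (MW,
rotatable bonds, HBA, HBD, PSA, logP) are z-scored with training-set
mean/SD stored in the model artifact and concatenated to the pooled vector
before the latent MLPs; output dimensions are unchanged. All six
properties are mandatory — partial wishlists would silently mean "average
molecule" for the missing entries.

**Decoder.** A two-layer LSTM whose layer-l hidden state is initialized by
l^l (cell states start at zero; the encoder emits exactly two vectors, so a
two-layer stack is the natural reading). Gates follow
g = σ(W_x k_t + b_x + W_l l_{t−1} + b_l) with separate input/recurrent
biases; the top hidden state is projected to logits over the token
alphabet. Training is teacher-forced cross-entropy with pad positions
masked, Adam (lr 10⁻³ default, batch 64), fully seeded; a non-finite loss
aborts with diagnostics.

**Alphabet.** Corpus tokens are harvested from the canonical form plus ten
randomized renderings per molecule so tokens unique to non-canonical
orderings are covered. Bracket atoms, `%nn` ring closures, Cl/Br and a
configurable list of functional-group strings (sulfoxide, nitro, carbonyl,
nitrile by default) are single tokens; start/end/pad markers are "x", "y",
"z" (SMILES) or [\X], [\Y], [\Z] (SELFIES). Tokenization is greedy
longest-match and round-trips exactly. SELFIES support is tokenizer-level
only (strings already in SELFIES form); SMILES↔SELFIES conversion would
require an external library that is not a dependency of this package.

**Sampling.** Token-by-token with the temperature softmax; T ∈
{0.2, 0.5, 0.8, 1.1} are the canonical operating points and T = 0.5 the
default. Invalid strings are returned with a validity flag, never raised.
`max_len` defaults to 100 tokens (the training corpus is capped at 97
characters).

**Dimensions.** All widths are config-driven. The default profile
(node 128, hidden 256, latent 256) is deliberately modest; published
full-scale models report ~3.5 M encoder + ~3.5 M decoder parameters, and
`count_parameters` exists precisely so users can match a published total
once its dimensions are known. Parameter totals are a reporting utility,
not a correctness gate.

**Why numpy + in-repo autodiff.** The deployment environment provides no
deep-learning framework, and the model itself (three message-passing
layers, attention pooling, a two-layer LSTM) needs only a dozen primitive
operations. `molcraft.autodiff` implements exactly those, with every
gradient checked against central finite differences in the test suite.
Batched graphs are packed into flat node/edge arrays with segment ids (the
standard trick), so training runs in minutes on one CPU at desk scale.

## QSAR scoring

Kernel ridge regression with the Laplacian kernel
k(x_i, x_j) = exp(−‖x_i − x_j‖₁/σ): α = (K + λI)⁻¹y, ŷ_q = Σ α_i k(x_i, x_q).
σ = 51.2 and λ = 10⁻⁷ are the screened defaults. The solver verifies its
residual to 1e-8 (relative) and converts a singular system at λ = 0 into an
actionable error. Descriptors:

- **ECFP4-512**: Morgan radius 2 hashed to 512 bits.
- **CATS**: 6 pharmacophore types (donor, acceptor, positive, negative,
  lipophilic, aromatic — assigned from the standard chemical-feature
  definitions) × 21 unordered type pairs × 10 topological distance bins
  (0–9 bonds, longer paths clipped into the last bin) = 210 absolute
  counts, unscaled. Two types on the same atom count once per unordered
  pair at distance 0. The binning is frozen and documented here because
  "absolute feature frequencies" admits several binnings; the choice is
  configurable only by editing one table.
- **USRCAT**: 60 shape-pharmacophore moments from a single seeded ETKDG
  conformer (seed 7, recorded; conformer failure is an error naming the
  molecule).

The ensemble score is the weighted mean (2·ŷ_ECFP + ŷ_CATS + ŷ_USRCAT)/4 —
"double-weighted ECFP" read as a weighted *mean*, not a sum divided by 3;
the weight vector is a parameter, and (1,1,1) recovers the arithmetic mean.
"Predicted affinity ≤ 1 µM" is implemented as ensemble pActivity ≥ 6.0.

## Novelty

S_ECFP is the Jaccard distance (1 − Tanimoto) to the nearest training
fingerprint, found by exact linear scan (any accelerated index must return
identical results). S_atom and S_carbon are 0.1 each iff the molecule's
Murcko scaffold / carbon skeleton (all heavy atoms → C, all bonds →
single) is absent from the training scaffold sets, else 0.
S_novelty = S_ECFP + S_atom + S_carbon ∈ [0, 1.2]. Acyclic molecules have
an *empty* scaffold, and the empty scaffold counts as present iff any
training molecule is acyclic — otherwise every trivial chain would earn a
spurious +0.2. Two all-zero fingerprints are treated as identical
(distance 0) inside the index; the standalone `jaccard_distance` raises on
that undefined case.

The synthesizability scorer is a pluggable interface; the shipped stub is a
fragment-complexity heuristic (size, ring count, stereocentres,
spiro/bridgehead atoms, macrocycles → penalty, clipped to [0, 1]). It is a
stand-in for an external retrosynthetic-accessibility classifier, adequate
for exercising the pipeline, not for real prioritization.

## Pipeline conventions

- Percentages in library reports are over *all* sampled strings; invalid
  strings count in denominators and satisfy no criterion. Uniqueness is on
  canonical SMILES; deduplication happens immediately after parsing.
- Two novelty thresholds coexist by design: library reports use ≥ 0.65,
  campaign filtering uses ≥ 0.7. Both are plain config values.
- Ranking is by weighted-mean per-target ensemble pActivity, ties broken by
  canonical SMILES so rankings are total and reproducible. Re-ranking a
  ranking is the identity.
- Campaign artifacts (designs CSV, report JSON, JSON-lines log with
  per-stage counts) embed the seed; the same config + seed reproduces the
  CSV byte-identically.

## Synthetic data: what it emulates, what it does not

`gen_interactome` decorates ring scaffolds (one per target) with a fixed
substituent grammar, so same-target ligands share a scaffold and
cross-target ligands mostly do not; affinities are log-uniform with a
configurable fraction above the 200 nM cutoff. Defaults (5 targets, 8
ligands/target, affinities 1–2000 nM, 25% above cutoff) give a table where
every curation rule has work to do. `gen_property_set` enumerates
ring-prefix + alkyl-chain + terminal-group molecules whose molecular weight
spans > 200 g·mol⁻¹. `gen_pocket` emits a PDB/SDF pair whose pocket
membership (7 atoms within 5 Å) and radius-edge count (2 edges ≤ 4 Å)
are fixed by construction, with B factors in the standard column.

These sets are *regular by design*: real bioactivity data has assay noise,
activity cliffs, scaffold promiscuity and heavy-tailed size distributions
that the grammar does not reproduce. A green test therefore establishes
that the machinery is correct (filters, graph assembly, training dynamics,
conditioning, scoring algebra) — not that the model would reach the same
quality on a public-database-scale interactome.

### The property-translation experiment

The scaled-down conditioning check trains on ~2,000 synthetic molecules for
20 epochs and samples 500 molecules at T = 0.5 with wishlists resampled
from the training profiles, then correlates recomputed molecular weight
against the wished one. Training pairs deliberately use a *different*
molecule of the family as encoder input than the decoding target, with the
wishlist holding the target's profile — mirroring the interactome training
setup, where input and output molecules differ and the wishlist describes
the output. If input and output were the same molecule, the encoder alone
could predict the target and the model would be free to ignore the
wishlist; the cyclic pairing makes the wishlist the only signal that
determines the output, so the measured correlation reflects conditioning.
Small dimensions (node 24, hidden 64, latent 96) keep the run at a few
minutes on one CPU.

## Numerical choices and degenerate inputs

- Boundary distances exactly at 5 Å (pocket) and 4 Å (edges) are included;
  the KD-tree pair query is padded by a 1e-9 relative factor and re-checked
  exactly, so boundary pairs are never lost to floating-point pruning.
- Cutoff comparison at 200 nM uses a 1e-12 tolerance on the pActivity scale
  to keep the inclusive boundary robust to log-roundtrip error.
- float64 everywhere in the neural stack; sampling uses inverse-CDF draws
  from a seeded PCG64 generator, so every artifact is reproducible from its
  seed. Seeds derived from user seeds stay below 2³¹.
- Empty graphs, empty pockets, empty training indexes, an all-zero
  fingerprint pair, and a singular kernel system each raise typed,
  actionable errors; an empty curated interactome and an empty survivor set
  are *values* (with diagnostics/warnings), because both are legitimate
  outcomes of strict filters.

## Known limitations

- SELFIES is supported at the token level only; no SMILES↔SELFIES
  conversion ships with the package.
- The pocket B factor is read from the file; no flexibility model is
  computed.
- The synthesizability stub is a heuristic, not a trained classifier.
- The CATS typing follows one fixed feature-definition file; other CATS
  implementations bin and scale differently and will not be numerically
  comparable.
- No docking, free-energy rescoring, transfer/reinforcement learning, or
  database connectivity.
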
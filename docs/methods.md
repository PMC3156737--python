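# Methods

This note documents the models and algorithms implemented in `fapscreen`,
the defaults chosen where the method leaves them open, and what the
synthetic-data generators do and do not emulate.

## Conformational space encoding

A molecule is reduced to its heavy-atom graph; hydrogen counts are recorded
per atom before suppression. Every unordered atom pair is classified once,
topologically:

- A bond is **rotatable** iff it is a single, non-aromatic bond outside any
  ring. Ring membership is cycle membership of the graph; amide C–N bonds
  count as rotatable (no special case).
- The pair's shortest bond path is found by BFS; when several shortest paths
  exist, the deterministic one found from the lower-index atom with
  neighbors visited in ascending index order is used. Only the *count* of
  rotatable bonds matters downstream, and tied shortest paths in molecular
  graphs essentially always run through equivalent ring arcs, so this
  convention removes nondeterminism without biasing the count.
- Rotatable bonds incident to either endpoint are *terminal* for that pair:
  rotating them does not change the pair distance, so they are excluded.
- The pair is **flexible** iff the internal rotatable-bond count is ≥ 1;
  otherwise **rigid**. Rigid pairs store their topological distance,
  flexible pairs get a distance model.

## Boltzmann weighting

Conformer n receives probability p(E_n) = exp(−ΔE_n/RT) / Σ_m exp(−ΔE_m/RT)
with ΔE_n the offset from the ensemble minimum (computed min-shifted, so the
exponentials cannot overflow and the weights are invariant to constant
energy shifts). Defaults: T = 300 K and R = 1.9872041×10⁻³ kcal/(mol·K),
i.e. energies are read as kcal/mol. These are package defaults for typical
force-field output — the temperature of the canonical ensemble and the
energy unit are configuration, paired in one object so the gas constant
always matches the unit. `uniform_weights=True` disables the weighting.

## Weighted EM

Each flexible pair's distance profile x₁…x_N with weights p(E_n) is fitted
with a univariate Gaussian mixture maximizing the weighted objective
L = N · Σ_n p(E_n) log Σ_c π_c N(x_n | μ_c, σ_c²). The N-scaling makes
uniform weights reduce the objective — and, because a single code path
implements both, the entire fit, bit for bit — to the plain maximum
likelihood case. The E-step is the usual responsibility computation; the
M-step uses weighted sufficient statistics:

    π_k  = Σ_n p(E_n) γ_nk
    μ_k  = Σ_n p(E_n) γ_nk x_n / Σ_n p(E_n) γ_nk
    σ_k² = Σ_n p(E_n) γ_nk (x_n − μ_k)² / Σ_n p(E_n) γ_nk

Numerical choices:

- **Component count.** One component per internal rotatable bond on the
  pair's path (capped by sample count and an optional `c_max`). This
  topological heuristic replaces per-pair BIC/AIC model selection, which
  would multiply preprocessing cost; an information-criterion selector can
  be layered on by the user but is deliberately not the default.
- **Initialization.** Means at evenly spaced weighted quantiles of the
  samples; variances at sample variance / C; uniform component weights.
  Restart r > 0 jitters the means with seeded Gaussian noise of 0.1× the
  sample standard deviation. Default 3 restarts, best final objective wins.
- **Convergence.** Relative objective change ≤ 1e-6 or 200 iterations.
- **Variance floor** 1e-4 Ų, applied every M-step: flexible pairs can be
  geometrically near-rigid, and the floor prevents likelihood blow-up on
  near-constant profiles. An all-identical profile collapses to a single
  component at the floor, whatever C was requested.
- **Empty components** (weighted responsibility mass < 1e-12) are removed
  and the remaining weights renormalized — deterministic and conservative,
  rather than reseeding.
- **Canonical sample order.** Profiles are sorted by distance (weights
  paired) before fitting, and each pair's EM seed is derived from the
  configured seed plus the pair indices, so conformer file order can never
  change an encoding.

## Similarity function

Atom labels are (element, ring flag, #heavy neighbors − #hydrogens);
equality is exact on the triple. Each atom roots a prefix tree over all
pairs to the other atoms, split into rigid (R) and flexible (F) sub-trees.

- **Rigid kernel:** multiset Tanimoto over (label, topological distance)
  items, |i∩j| / (|R_i| + |R_j| − |i∩j|) with min-count intersection.
- **Flexible kernel:** raw(F_i, F_j) = Σ_m Σ_n δ(l_m, l_n) · corr(g_m, g_n),
  where corr is the normalized cross-correlation of mixture densities,
  ⟨g,h⟩/√(⟨g,g⟩⟨h,h⟩), with ⟨g,h⟩ = Σ_cd π_c π_d N(μ_c | μ_d, σ_c²+σ_d²) in
  closed form. The raw sum is normalized by cosine self-normalization,
  raw/√(raw(F_i,F_i)·raw(F_j,F_j)), bounding it by 1 with equality for
  identical sub-trees (a leaf-count normalization is selectable). The
  normalized cross-correlation was chosen as the correlation measure on
  mixtures because it is the standard density correlation, has a closed
  form, lies in (0, 1], and is 1 exactly for identical models; a
  Pearson-style alternative would subtract density means and lose the
  closed form.
- **Combination:** S^ij = 0.5·rigid + 0.5·flex. A plain (1, 1) sum would
  put entries in [0, 2] and break the final score's [0, 1] range under any
  count normalization, so the equal-weight average is the default and the
  literal sum sits behind `literal_sum=True`. When a molecule pair has no
  flexible pairs at all, the full weight shifts to the rigid kernel (and
  symmetrically), so all-rigid molecules compare by their rigid trees alone.
- **Empty sub-trees:** both empty → 1, exactly one empty → 0. This keeps
  self-similarity at 1 for every molecule, including single-atom ones.
- **Final score (OA variant):** a maximum-weight injective assignment of
  trees (rectangular Hungarian algorithm) over the |A|×|B| matrix, with the
  total divided by max(|A|, |B|). At most min(|A|, |B|) entries ≤ 1 are
  assigned, so the score is in [0, 1], penalizes size mismatch, and is 1
  exactly on self-comparison. Division by min(|A|, |B|) is selectable. The
  **sum variant**, kept for QSAR-style model building and comparison
  experiments, is the mean of all matrix entries.
- **Exact symmetry.** Mixture correlations are evaluated in a canonical
  argument order and all kernel sums use exactly rounded summation
  (`math.fsum`), so swapping the two molecules returns the identical
  floating-point score.

Assignment ties are broken by the deterministic solver; tied assignments
share the same total. Known limitation: the optimal assignment maximizes
leaf-level similarity and is free to make topologically inconsistent atom
correspondences (assignments that do not preserve a substructure mapping);
no repair step is attempted.

## Screening metrics

AUC follows the decoys-ranked-above-actives formulation,
1 − (Σ_i d_i)/(N_a·N_d). Ties between an active and a decoy score count
half, making the value exactly the Mann–Whitney U estimator; strict counting
is available. Selection sizes use N_sel = ceil(x%·N). REF is
100·TP/min(N_sel, N_a), which is 100 for a perfect ranking at any fraction.
ROCE takes the TPR at the first rank where the FPR reaches x% (no
interpolation). awROCE weights each retrieved active by 1/N_j (its chemotype
cluster's size) and averages over clusters, reducing exactly to ROCE for
singleton clusters. BEDROC follows the Truchon–Bayly closed form.

## Synthetic data

The fixtures module replaces conformer generation and force-field scoring,
which are outside this package's scope:

- **Coordinate mode** builds alkane-chain conformers with fixed bond
  lengths (1.54 Å) and angles (112°) and torsions drawn from noisy
  trans/gauche rotamer states, plus a rigid planar benzene — enough to
  exercise the full SDF → profiles → encoding path with real geometry.
- **Direct mode** samples each flexible pair's distances exactly from a
  planted Gaussian mixture (default: one component per internal rotatable
  bond, means 2.5 Å apart starting at 3 Å, variance 0.09 Ų) and derives
  conformer energies from a stated function of the sampled distances
  (default: zero coupling and zero noise, i.e. an equal-energy ensemble).
  Planted structure gives recovery tests an exact ground truth.
- **Screening sets** spawn chemotype prototypes as strong perturbations of
  one query molecule and actives as mild perturbations of prototypes
  (default: 30 actives in 5 chemotypes, 300 decoys, 5–10 atoms, mean jitter
  0.8 Å between chemotypes and 0.25 Å within, small label-edit
  probabilities); decoys are independent random molecules.

What this does *not* emulate: real conformational sampling density (a
production workflow would sample conformers down to ~0.1 Å rmsd resolution
and score them with a force field), property-matched decoys, correlated
energy landscapes, or the
chemical diversity of real screening libraries. Passing tests demonstrate
that the machinery — classification, weighted fitting, kernels, assignment,
metrics — is correct on data with known structure; they do not measure
retrospective screening performance on real benchmarks, which additionally
depends on the conformer generator and force field used upstream.

## Problem sizes

The test suite and acceptance script run at desk scale by design: mixture
recovery at n = 2000 samples, 100–1000 randomized trials per property,
screening sets of a few hundred molecules of 3–12 atoms. These sizes give
stable statistics for every assertion while keeping a full run in seconds.
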
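# Methods

## Google matrix and ranking

A directed network of `N` nodes is held as a binary adjacency in the
column-as-source convention, `A[i, j] = 1` when node `j` cites node `i`;
duplicate links collapse and self-loops are dropped at load time.  The
Markov transition matrix is `S[:, j] = A[:, j] / k_out(j)` for citing
columns and the uniform column `1/N` for dangling nodes (`k_out = 0`).
The Google matrix `G = alpha * S + (1 - alpha)/N` is kept as a
sparse-plus-rank-one operator (link part, dangling rank-one part, uniform
teleport); all operations behave exactly as if the dense matrix existed,
and the dense form is materialized only for desk-scale matrices and
sub-blocks.

PageRank is the unit-eigenvalue right eigenvector of `G`, computed by
power iteration from the uniform vector with an L1 stopping tolerance of
`1e-12` (default cap 1000 iterations; the damped spectral gap makes ~200
iterations typical at alpha = 0.85).  The tolerance is deliberately far
below rank-resolution needs so that rank orders of desk-scale networks are
stable.  CheiRank is the PageRank of the link-inverted network; the
implementation literally inverts the link set and reuses the same code
path, which the tests exploit as a definitional identity.  Rank indices K
are 1-based; ties (exactly equal probabilities) break by ascending node
index so every ordering is deterministic.  Local subset indices `K_r` are
the restriction of the global order to a subset, with per-category
sub-indices for mixed subsets.

Default damping is the standard `alpha = 0.85`.  Rankings of
hub-dominated networks are insensitive to alpha across 0.5–0.95, which is
checked on the synthetic hub scenario rather than assumed.

## Reduced Google matrix

For a subset `r` of `N_r` nodes with complement `s`, the blocks
`G_rr, G_rs, G_sr, G_ss` give the reduced matrix

    G_R = G_rr + G_rs (1 - G_ss)^-1 G_sr

whose stationary vector reproduces the global PageRank restricted to the
subset and renormalized — the method's defining contract, enforced in the
tests at `1e-9`.  Two computations are provided:

- **direct** (default): one dense linear solve against `(1 - G_ss)`.
  Exact at desk scale and cheapest.  The `G_pr` term is then split off
  using the leading eigenpair of `G_ss` and `G_qr` obtained by
  subtraction.
- **spectral**: with the leading eigenvalue `lambda_c` of `G_ss` and its
  right/left eigenvectors `psi_R`, `psi_L` (normalized `sum(psi_R) = 1`,
  `psi_L . psi_R = 1`), projector `P_c = psi_R psi_L^T`, `Q_c = 1 - P_c`
  and `Gbar_ss = Q_c G_ss Q_c`:

        G_pr = G_rs [P_c / (1 - lambda_c)] G_sr
        G_qr = G_rs Q_c (1 - Gbar_ss)^-1 Q_c G_sr

  The bulk resolvent is evaluated by a linear solve or, optionally, by the
  truncated geometric series with a tail bound below `1e-12` (the running
  term ratio gives the geometric tail estimate; the truncation depth is
  recorded on the result).  `Gbar_ss` contracts at roughly `alpha` per
  power, so depths around 170 are typical.

Both routes must agree entrywise to `1e-10`; this cross-check runs over
hundreds of random networks in the acceptance battery.  The leading
eigenpair comes from a dense two-sided `eig` up to complement size 1500
and from sparse Arnoldi iterations above.  A leading-eigenvalue modulus
gap below `1e-8` raises an explicit error rather than silently picking an
eigenvector: the `G_pr`/`G_qr` split is ill-defined there.  For a genuine
damped Google matrix the complement block is strictly positive, so its
Perron eigenvalue is simple and this guard never fires in practice.

`G_qr = G_qrd + G_qrnd` splits into the diagonal and the off-diagonal
(hidden-link) parts.  An entry of `G_rr` counts as a direct link when it
exceeds the teleport floor `(1 - alpha)/N` plus `1e-15` slack, which is in
one-to-one correspondence with the restricted adjacency; a **hidden link**
is a positive `G_qrnd` entry at a pair with no direct link.  The default
hidden-link threshold is exactly zero because the restricted adjacency
provides the exact structural zeros.  The degenerate full-subset case
`N_r = N` is defined as `G_R = G_rr = G` with `G_pr = G_qr = 0`.

Reduced matrices are computed from dense blocks, which bounds the
practical global size to a few thousand nodes on one machine; complements
beyond the dense-solve range are out of scope by design.

## PageRank sensitivity

A link `b -> a` of `G_R` is perturbed by multiplying `(G_R)[a, b]` by
`(1 + delta)` and renormalizing column `b` to unit sum.  The sensitivity
of an observed node `c` is `D = d ln P(c) / d delta`, evaluated by finite
differences on the `N_r`-dimensional reduced PageRank (not by re-running
the global network): the perturbation is defined on reduced-matrix
elements, so the derivative belongs to the reduced operator.  The default
is the central scheme at `delta = 1e-4` — second-order accurate without an
analytic resolvent derivative — with the forward scheme and the step size
exposed.  Central differences at `delta = 1e-3` and `1e-4` agree to three
significant digits on random instances, and a `delta = 0` perturbation is
an exact identity; both properties are asserted.  Reduced PageRanks inside
the derivative use a `1e-14` power-iteration tolerance so that the
differenced logarithms retain full precision at `delta = 1e-4`.  Note that
because of the column renormalization, boosting an element that already
dominates its column has a *suppressed* diagonal sensitivity; D is largest
for links that are strong relative to the observed node's other inputs,
not for the largest matrix element per se.

Structural zeros are not perturbable: the scalar operation raises an
error, and the matrix operation reports NaN ("absent"), never `D = 0`,
to keep "no link" distinct from "insensitive".

## Friend networks and partner tables

The interaction score of a candidate link `j -> i` within the subset is
`(G_rr + G_qrnd)[i, j]` — direct plus off-diagonal indirect weight.  From
seed nodes, each node's `n_friends` strongest same-category partners are
attached; each later iteration expands only the nodes newly added in the
previous one (breadth-first), stopping at the first iteration that adds no
new node (termination is guaranteed by monotone growth over a finite set;
`max_iter` is a safety valve only).  Finally every primary-category node
receives its `n_attach` strongest partners from each attached category
(e.g. countries, drugs); attached nodes are never expanded.  Edges are
classified `direct` when the restricted adjacency has the link and
`hidden` otherwise, and every hidden edge is cross-checked against the
adjacency on every build.  Score ties break by ascending local PageRank
index (more influential first), and a node never appears in its own
friend list.  Both score variants `rr_plus_qrnd` and `rr_plus_qr` are
supported for partner tables since either convention is defensible; the
choice is a parameter rather than a constant.

Exports: a lossless `edge-tsv` dialect (nodes and edges with category,
iteration, kind and full-precision weights), GraphML with typed node/edge
attributes, and DOT.  All exports are byte-deterministic.

## Ranked-list overlap

`eta(j)` counts the labels common to the top `j` of two ranked lists.
Labels pass through an explicit, versioned canonicalization table before
comparison (apostrophe variants, "Hodgkin's"/"Hodgkin", abbreviations such
as "NETs"/"GTD", bare names completed to "... cancer"); a collision
introduced by canonicalization is an error, not a silent merge, and
"Melanoma" and "Skin cancer" are deliberately distinct labels.  The
packaged fixtures transcribe printed rankings with canonical labels: the
mixed 240-entry Wikipedia-derived PageRank order of cancer types and drugs
(with its cancers-only and drugs-only sub-orders), the alphabetical
37-cancer and 203-drug lists, and the four epidemiology rankings
(GBD-2017 deaths and DALYs, GLOBOCAN-2018 deaths and new cases, 24
entries each, values in thousands per year).

## Synthetic networks

The generator's contract is to reproduce the qualitative structure the
analysis relies on, not any specific real network:

- **background** (`n_background`, default 300): directed preferential
  attachment — each new node cites `m_out = 3` earlier nodes chosen with
  probability proportional to in-degree + 1, and receives a link from a
  random elder with probability 0.3 — yielding a heavy-tailed in-degree
  distribution;
- **hubs** (country analogs, default 3): each background node cites each
  hub with probability 0.4, placing hubs at the top of PageRank;
- **groups** (cancer/drug analogs): each group node receives links from a
  fraction `in_rate` of the background and cites a fraction `out_rate`
  (defaults 0.12/0.04 for the 8 cancer analogs and 0.04/0.08 for the 12
  drug analogs), stratifying the groups between the hubs and the bulk;
- **planted indirect pathways**: fresh relay nodes carry
  `source -> relay(s) -> target` chains and any direct `source -> target`
  link is removed, giving hidden-link detection a ground truth.  A relay
  has out-degree one, so the two-hop transition amplitude
  `~ alpha^2 / k_out(source)` dominates the diffuse indirect background;
- **dangling nodes**: a configured fraction (default 5%) of background
  nodes has its out-links removed.

A fixed seed gives byte-identical edge lists (numpy `default_rng`,
PCG64, recorded in output manifests).  The stratification is verified
statistically: over 20 seeds, at least 18 must order the category median
PageRank indices hubs < cancer analogs < drug analogs, and a
shuffled-label control must fail that ordering in most runs.

What the generator does **not** emulate: textual/semantic correlation of
links, degree correlations beyond preferential attachment, communities in
the background, or the sheer scale of a real encyclopedia network.
Passing tests therefore demonstrate the *algorithms* (decomposition
identities, conservation laws, planted-structure recovery at desk scale),
not that any particular real-world ranking would be reproduced.

## Problem sizes and numerical choices

The verification suite and acceptance script run entirely at desk scale,
chosen so the whole battery completes in seconds while still exercising
every code path: 200 random networks with `N <= 60`, `N_r <= 12` for the
method-agreement contract; 50 seeded generator configurations
(background 150, 8-entity group, one planted two-hop path) for hidden-link
recovery; 8 ten-node reduced matrices for the sensitivity scheme check.
Tolerances: method agreement `1e-10`, PageRank conservation `1e-9`,
weight-sum identity `1e-9`, sensitivity scheme agreement three significant
digits, zero-perturbation identity `1e-14`.

## Known limitations

- Dense complement algebra bounds the global network size; there is no
  out-of-core or approximate REGOMAX path.
- `G_qr` entries can be slightly negative (the spectral projector is not
  positivity-preserving); hidden-link masks use strict positivity, so tiny
  negative indirect weights are never flagged.
- The friend-network attachment iteration number for satellites follows
  the owning node's iteration + 1; the printed-figure convention this
  mirrors is a drawing convention, and downstream consumers should rely on
  edge `kind` and `weight` rather than satellite iteration numbers.
- Sensitivity uses finite differences; an analytic resolvent derivative
  would be faster for large sensitivity grids and is a possible extension.
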
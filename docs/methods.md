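# Methods

## Setting

K study nodes hold horizontally partitioned data: the same variables,
disjoint individuals. A central analysis client may exchange only
aggregate statistics with the nodes; individual-level records, GPS
coordinates and genotype calls must never leave their custodian. All
communication crosses a mandatory JSON serialization boundary, so "only
aggregates travel" is a structural property rather than a convention:
anything a server operation returns is rendered to plain JSON, passed
through the node's disclosure guard, and logged.

## Federated generalized linear models

For a GLM with canonical link (gaussian/identity, binomial/logit,
poisson/log), IRLS touches the data only through the weighted
cross-products of the design matrix. With η = Xβ, μ = g⁻¹(η), weights
W = diag(V(μ)) and working response z = η + (y − μ)/V(μ), one update is

    β ← (X'WX)⁻¹ X'Wz.

Both X'WX and X'Wz are sums over rows, so each node k can return its own
share (a p×p matrix and a p-vector) and the client sums them. The federated
iteration is therefore *algebraically identical* to the pooled one — the
defining correctness property, verified in the test suite against both an
in-package pooled implementation and statsmodels, to 1e-6 relative and
usually to machine precision.

Numerical choices:

* start at β = 0; convergence when |dev_t − dev_{t−1}| / (|dev_t| + 0.1)
  < 1e-8; at most 25 iterations (standard IRLS practice). Non-convergence
  (e.g. perfect separation in logistic models) is flagged, not raised; the
  last iterate is returned with `converged = False`.
* binomial means are clipped to [1e-12, 1−1e-12] and log-link linear
  predictors to ±30 to keep weights finite; genuinely non-finite weights
  become an error status in the node's contribution.
* a singular summed information matrix (e.g. a constant covariate) raises
  "non-identifiable model".
* standard errors are √diag of the inverse summed information at
  convergence, scaled by the estimated dispersion deviance/(n−p) for the
  gaussian family (binomial and poisson have dispersion fixed at 1). This
  matches what a pooled `glm` fit reports.
* missing data: complete-case per model and per node; the per-node n used
  by the disclosure filters is the complete-case n.
* categorical covariates are treatment-coded against the lexicographically
  first level, deterministically; the client verifies that the design
  columns agree across nodes before iterating and aborts on any mismatch
  (nodes with disjoint level sets cannot be silently combined).

The deviance definitions are the standard saturated-model deviances per
family. Per-iteration payloads are re-guarded on every iteration; a node
whose policy blocks the fit aborts the whole fit with that node's
study-side messages.

## Disclosure model

Custodians configure one of three flavours per node:

* `off` — every check disabled (non-sensitive data);
* `minimal` — only raw-record egress is blocked;
* `full` (default) — all filters.

Filters and defaults:

| filter | default | applies in |
| --- | --- | --- |
| minimum non-empty contingency cell | 3 | full |
| observations per model parameter | 5 | full |
| minimum derived-subset size | 3 | full |
| raw-record egress (component length = n) | — | minimal, full |

The numeric thresholds are configurable per node and deliberately
conventional; they are not reachable through any client-facing operation.
Empty contingency cells pass the cell filter: a zero cell identifies
nobody, and filtering it would block sparse but harmless tabulations.

"Raw-record egress" is operationalised as: any payload containing a
sequence component, at any nesting depth, whose length equals the node's
record count. This is a heuristic — a deliberate over-approximation that
can in principle block a legitimate aggregate whose dimension coincides
with n (e.g. a scan over exactly n variants on n samples); the study
designs in this package keep those dimensions distinct. Under `full`
checks the payload must additionally match an approved aggregate shape
(scalar, vector of length ≤ p, matrix ≤ p×p, tabulation passing the cell
filter, or a mapping of these). The filters are monotone by construction:
everything blocked under `minimal` is blocked under `full`, and everything
allowed under `full` is allowed under the laxer modes — a property test
fuzzes this invariant.

No differential privacy, noise addition or output blurring is attempted.

## GWAS

Genotypes are held per node as a samples × variants matrix of
alternate-allele dosages (0/1/2, additive coding) with NaN for missing
calls, read from VCF 4.x (GT field; phasing ignored; multi-allelic records
rejected rather than silently split). Variant lists must be identical
across nodes; harmonisation (imputation, strand fixing) is out of scope
and a mismatch is a hard error.

QC keeps variants with pooled MAF ≥ 0.01 and pooled missing fraction
≤ 0.05 by default (both overridable); pooled allele frequencies are
computed from per-node allele and missingness tallies, which are
aggregate vectors over variants, not individuals.

Two association modes, both fitting outcome ~ covariates + dosage per
variant:

* `federated` — one distributed IRLS fit per variant: exactly the pooled
  analysis, at the cost of one network round per IRLS iteration per
  variant;
* `meta` — each node fits locally and returns only (β, SE, n, status) per
  variant; the client pools by inverse-variance fixed-effect weights in a
  single round. Fixed-effect inverse-variance is the documented default
  combiner; random-effects pooling is a possible extension.

p-values use the Wald statistic against the normal reference, standard
GWAS practice. Per-variant failures (non-convergence, disclosure blocks,
QC filtering) are recorded in a status column and do not stop the scan.
No population-stratification correction (PCs/GRM) is implemented.

## Geospatial exposure

Outlet points are buffered into regular 64-gon approximations of the
closed disc of radius r (vertices at angles 2πk/segments, polygon
inscribed in the circle; area deficit < 1% at 64 segments). An
individual's exposure count is the number of *distinct* buffers their
commute polyline intersects — repeated passes through one buffer count
once, and boundary contact counts as exposed. Coordinates are planar
Cartesian metres; geodetic data must be projected upstream; there is no
map matching or GPS noise filtering.

The pipeline runs entirely server-side per node: buffer → intersect →
count → join with the phenotype table on individual id; only the federated
GLM aggregates leave the node afterwards. An id mismatch between traces
and phenotypes is reported as counts of unmatched ids, never the ids
themselves. The intersection test is validated against a brute-force
oracle that densely samples each trace segment (step r/100) and compares
Euclidean distances; comparisons exclude closest approaches inside the
annulus (r·cos(π/64), r], where the inscribed polygon and the true circle
legitimately disagree.

## Synthetic studies

The generators are pure functions of (parameters, seed) and define the
study conditions end to end:

* **tabular** — standard-normal and Bernoulli(0.5) covariates; outcome
  drawn from the family's model at coefficients
  (0.5, x1 = 1.0, x2 = 0.5, bin1 = −0.5), gaussian residual sd 1;
* **genotype** — per-variant allele frequencies uniform on [0.05, 0.5]
  (shared across nodes), dosages in Hardy–Weinberg proportions
  (p², 2pq, q²); causal variants at MAF 0.3 with per-allele effect 0.4 on
  a unit-sd trait in the power design; optional missingness is
  missing-completely-at-random;
* **geospatial** — 810 individuals and 6100 outlets by default, in a
  10 km × 10 km region; outlets on a jittered grid; commutes as 12-vertex
  home-to-work polylines with Brownian-bridge noise (sd 80 m per step);
  buffer radius 50 m; BMI = 25 + 0.05·exposure + small age/sex/income/
  education/smoking effects + N(0, 3). The exposure column entering the
  outcome model is computed by the same geometry the pipeline uses, so
  end-to-end recovery tests the whole chain, not just the GLM.

What the generators do **not** emulate — and hence what passing tests do
not establish about field data: linkage disequilibrium and population
structure in the genotypes, road networks and temporally autocorrelated
GPS error in the traces, confounding between exposure and covariates, and
between-study heterogeneity (the meta-analysis mode is exercised under
homogeneity, where fixed-effect pooling is correct).

## Problem sizes

The test and acceptance runs use 3 nodes × 1000 samples for pooled
equivalence, 2000 null variants (3 × 500 samples) for the type-I error
check, 20 replicates of the 200-variant/5-causal power design, and the
full 810 × 6100 geospatial study — sizes chosen to make the statistical
checks sharp while keeping the whole suite in the tens of seconds on one
CPU.

## Known limitations

* The transport is in-process; a network transport can be plugged in
  behind the same request/response contract but is not provided.
* HTTP(S) resource locations resolve but do not fetch (desk scale is
  local-file and embedded-SQL only); SSH computation resources are out of
  scope — the shell client runs whitelisted *local* commands.
* The length-equals-n guard is heuristic (see above); disclosure control
  composes with, but does not replace, sound governance of the hosting
  environment.
* `GLMSpec` supports main effects only (no interactions, offsets or
  user-supplied weights); families are the three canonical-link ones.
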
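# Methods

This note records the models implemented in `prokit`, the parameter choices
behind them, the numerical conventions that affect results, and what the
synthetic fixtures do and do not demonstrate.

## Structure model and PDB handling

Structures are a flat list of residues (chain, author residue number,
insertion code) each holding its atoms, in file order.  Files may be
incomplete: numbering is taken verbatim, gaps are allowed, and HETATM
records are retained but excluded from residue-level property and network
computations unless explicitly requested.  For alternate locations the
highest-occupancy conformer is kept (ties go to file order), the standard
single-conformer convention.  Multi-model files contribute only their first
model.  Writing uses fixed PDB v3.3 columns, so coordinates round-trip at
the format's native 3-decimal precision; anything that would overflow a
column is an error rather than a silently corrupted file.

pLDDT extraction assumes the AlphaFold convention of one confidence value
per residue replicated on each atom's b-factor.  Disagreement above 1e-6
falls back to the per-residue mean with a warning; values outside [0, 100]
are passed through with a warning since experimental files store true
B-factors there.

## Annotation mapping

UniProt feature strings (`TYPE start..end; /qualifier="value"; ...`) are
parsed into typed site annotations with 1-based inclusive ranges.  Feature
keys map to seven categories: binding, active_site, ptm (MOD_RES, LIPID,
CARBOHYD, CROSSLNK), region (REGION, MOTIF), disorder (REGION features
whose note is "Disordered"), secondary_structure (HELIX/STRAND/TURN, with
the element kind kept as a qualifier), and other (DISULFID and anything
unrecognized).  Positions carrying UniProt's uncertainty syntax (`?`, `<`,
`>`) and inverted or non-numeric ranges are skipped and reported, never
guessed.

Projection assumes structure residue numbering equals UniProt sequence
numbering, which holds for AlphaFold models (1..N).  For experimental
structures with author renumbering the caller must renumber first.  The
residue table stores references to the original annotations, so ranges are
recoverable and the total number of residue entries equals the sum of the
annotation span lengths.  User columns are length-checked against the
sequence length at insertion; replacement of an existing column warns.

## SASA

Shrake–Rupley with a deterministic golden-spiral lattice; no randomness.
Defaults: probe 1.4 Å (water-sized), 960 points per atom.  960 is a
convergence compromise: the classic point count (92) leaves per-atom errors
of a few percent, while 960 brings the isolated-atom error well under 1%
and doubles runtime only linearly.  Van der Waals radii are Bondi values;
unknown elements get a carbon-like 1.70 Å default.

Two conventions matter numerically:

* A test point exactly on a neighbor's expanded sphere counts as exposed
  (strict inequality for burial), which matches the analytic spherical-cap
  limit for two touching spheres.
* The lattice is oriented in the structure's principal-axes frame, with
  eigenvector signs fixed by the third coordinate moment (falling back to
  the most distant atom's side when the distribution is symmetric).  A
  lab-frame lattice would make SASA depend on the molecule's orientation at
  the discretization-error level (~1%); the canonical frame makes areas
  invariant under rigid motion up to floating-point rounding.  Structures
  with fewer than three atoms use the identity frame.

Relative exposure divides residue SASA by the residue type's theoretical
maximum (Tien et al. 2013 values); non-standard residues use the table
median.

## Bond perception and Gasteiger (PEOE) charges

Bonds are perceived from distances: bonded iff
`0.4 Å < d ≤ r_cov(i) + r_cov(j) + 0.45 Å` with Cordero covalent radii.
This recovers textbook connectivity at ideal geometry but assigns no bond
orders.

PEOE uses the original Gasteiger–Marsili coefficients per
element/hybridization class, zero initial charges (neutral molecules), six
iterations with `(½)ⁿ` damping, and the donor's cation electronegativity
(`a + b + c`; 20.02 for hydrogen) as the normalizer.  Updates within an
iteration are synchronous.  Charge is conserved exactly by construction.

Hybridization comes from a curated table for standard amino-acid atom
names (backbone carbonyl sp², aromatic rings sp², guanidinium and amide
nitrogens sp², etc.); other atoms fall back to element + bonded degree,
which is reliable when hydrogens are explicit.  Hydrogen-free structures
(AlphaFold models) are accepted — the curated table still classifies their
heavy atoms correctly — but a warning recommends explicit hydrogens for
quantitative use, since the missing H charges change heavy-atom values.
Atoms with no published coefficients (metals) are excluded and reported
rather than guessed.

An independent reference implementation of the same model (OpenBabel's
`gasteiger` charges) run on the ideal-geometry ethanol fixture agrees with
this implementation within 4e-5 per atom; the tests assert 5e-3, which
also absorbs the minor convergence-depth differences between PEOE
implementations.

## pKa and protonation

The native pKa model is a deliberately transparent two-term heuristic:
model-compound pKa per group plus a burial shift of +2.0 (acids: Asp, Glu,
Cys, Tyr, C-terminus) or −2.0 (bases: His, Lys, Arg, N-terminus) when the
residue's relative SASA is below 0.2.  The shift magnitude and threshold
are order-of-magnitude choices consistent with observed desolvation
shifts; the model ignores electrostatic coupling between sites, hydrogen
bonding, and conformational response, so it is a screen, not a predictor.
Chain termini are titratable sites of the first/last polymer residue per
chain.  Externally computed pKa values (PROPKA and similar) are first-class
citizens through a CSV adapter and flow through the same protonation code.

Protonated fraction is Henderson–Hasselbalch, `1/(1 + 10^(pH − pKa))`,
exactly 0.5 at pH = pKa; the integer assignment calls a site protonated at
fraction ≥ 0.5.

## Distance networks and backbones

The inter-residue distance convention is configurable because published
edge counts depend on it: `closest_atom` (minimum over heavy-atom pairs,
the common contact-map convention, default) or `c_alpha`.  Hydrogens never
participate, so protonated and unprotonated inputs give identical networks.
Edges are included at distance ≤ cutoff (closed boundary); isolated
residues remain as nodes; sequence-adjacent pairs are *not* excluded by
default (an optional `min_separation` exists).  Thresholding may only
lower the cutoff — raising it cannot recreate unknown edges and is an
error.

Backbone sparsification removes an edge of weight `d` iff some path
between its endpoints has p-norm length strictly less than `d`; equality
keeps the edge (the 3-4-5 right triangle keeps all three edges at p = 2).
Because every path through an edge is at least as long as the edge itself
under any p-norm, the test reduces to comparing `d` with the all-pairs
shortest p-length, computed as ordinary Dijkstra on weights raised to the
p-th power for finite p (minimizing `Σ dᵢᵖ` minimizes `(Σ dᵢᵖ)^(1/p)`),
and as minimax distances over the minimum spanning forest for p = ∞ (the
classic bottleneck-shortest-path identity).  Comparisons are done in the
transformed domain (`Σ dᵢᵖ` vs `dᵖ`), so implementation and the exhaustive
path-enumeration oracle used in tests see identical floating-point values.
Consequences verified by property tests: the kept subgraph preserves
connected components exactly, kept sets are nested (p = ∞ ⊆ p = 2 ⊆ p = 1),
and the backbone is idempotent.

Region graphs put one node per selected annotation (regions, binding
sites, active sites, PTM sites), weight edges by the minimum heavy-atom
distance between residue sets (0 when sets overlap), and drop annotations
with no structurally resolved residue (with a warning).  No maximum
distance is applied by default.

## Tabular export and color schemes

Property tables are pandas DataFrames with one row per residue; properties
not computed for a residue are explicit missing values and render as empty
CSV/TSV fields.  The per-residue pKa column reports the side-chain site;
terminal sites appear only for residues without a titratable side chain,
with the group recorded alongside.

Color schemes are linear interpolations between fixed anchor colors: a
pale-to-dark green sequential ramp (monotone in every RGB channel, hence
order-preserving in luminance) and a blue–white–red diverging ramp around a
midpoint (defaulting to the centre of the value range; pass 7 for pKa or 0
for charge).  Missing values map to neutral gray `#808080`.  Quantization
to 8-bit channels can merge values closer than ~1/255 of the range.

## Synthetic fixtures: what they show and what they do not

The fixtures provide analytic ground truth: collinear Cα chains (exact
pairwise distances, hand-countable edge sets), cysteine pairs with an exact
SG–SG distance, ideal-geometry toy molecules with explicit hydrogens
(known bond graphs and symmetry classes), and seeded UniProt-style TSV
tables with known annotations including deliberately malformed entries.
They are deterministic and survive PDB round-trips at column precision.

They are not physically realistic proteins: no packing, no secondary
structure, no Ramachandran validity.  Passing tests therefore demonstrate
algorithmic correctness (geometry, graph theory, parsing, closed forms),
not predictive accuracy of, say, the pKa heuristic on real proteins.  The
backbone implementation is additionally validated against exhaustive
simple-path enumeration on 200 seeded random weighted graphs of up to 8
nodes — small enough for the oracle to be exact, varied enough to exercise
ties, dense triangles, and near-bridges.

## Known limitations

* No mmCIF input; NMR ensembles use the first model only.
* Gasteiger charges on hydrogen-free inputs are qualitative; formal
  charges are not perceived (all molecules treated as neutral).
* The native pKa model ignores site–site coupling; use the external
  adapter for quantitative work.
* UniProt positions with uncertainty syntax are skipped, not modelled.
* Region-graph distances are minimum-atom distances; centroid or
  size-weighted alternatives are not implemented.
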
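# Methods

## Contact networks from trajectory ensembles

A *contact* is a pair of selected atoms whose Euclidean distance is at most
the cutoff (default 5 Å, the standard choice for protein structure
networks). The predicate is a closed ball (`<= cutoff`): the boundary
convention matters for bit-reproducibility, and the closed form matches the
semantics of KD-tree neighbor queries, which the implementation uses
(`scipy.spatial.cKDTree.query_pairs`). The default atom selection is the
protein stripped of hydrogen atoms; hydrogens are recognized by the element
field when present, otherwise by the first letter of the atom name after
stripping leading digits (PDB conventions such as `1HB` vary across
topologies). Backbone-only and sidechain-only selections are provided for
atom-class subnetworks — these must be re-projected from the atomic
matrices with the corresponding selection, not filtered at the residue
level.

Per-frame binary atomic contact matrices are averaged over all frames of an
ensemble; frames pooled from several replica files carry equal weight.
Averages are computed as a single division of integer per-pair contact
counts by the frame count, so each entry is the exact rational *k/F* with
no accumulation error. The projection onto residues uses the binary
incidence matrix *T* (*t*ᵢⱼ = 1 iff atom *i* belongs to residue *j*,
deselected atoms giving all-zero rows): *R* = *Tᵗ A T*, with the diagonal
zeroed because intra-residue contacts are not part of the analysis. In the
single-selection pipeline the integer counts are projected first and
divided by *F* last, which keeps *R* bitwise symmetric and exact; in the
general routine (which admits different row and column selections for
asymmetric contacts) the result is explicitly symmetrized when the two
transformations coincide, to undo the ~1 ulp asymmetry of float matrix
multiplication. Periodic-boundary re-imaging is out of scope: frames are
assumed whole-molecule imaged, and a guard warns when a frame ensemble's
bounding box is implausibly small for its atom count.

## The perturbation network

The DPCN adjacency matrix is the difference *R*(final) − *R*(initial),
taken between two states with identical residue label sets
(`chain:resseq:resname`; any mismatch is rejected listing the symmetric
difference). Residue pairs whose mean contact count is unchanged are not
stored; an `epsilon` parameter (default 0) can additionally suppress tiny
differences. The sign convention is pinned by the rendering rule — blue
edges have more contacts in the initial state (negative weight), red in
the final state — and all thresholding, the top-k baseline and the sweep
operate on magnitudes; signs are carried only as edge attributes for
display. The top-k baseline keeps all edges tied with the k-th magnitude
rather than truncating arbitrarily, and reports a flag when that happens.

## Connected-component analysis

Edges are removed one at a time in ascending magnitude; equal magnitudes
are broken by lexicographic endpoint labels, so the trace is deterministic
and byte-identical across runs. After each removal, degree-0 nodes are
pruned (and never return) and components are counted by breadth-first
search (NetworkX). Each single removal is one trace step; steps that finish
a magnitude tie group are flagged as level boundaries, and the
count-versus-weight curve is read at those boundaries plus the initial
state. Level *w* thus denotes the graph retaining exactly the edges with
magnitude ≥ *w* — the "smallest weight left in the graph".

The final CC structure is taken at the largest level attaining the global
maximum of the level curve. Resolving "latest occurrence" at magnitude
level rather than at individual steps is deliberate: within a tie group the
intermediate states depend on the (arbitrary) tie order, while the
post-group state does not, so the critical weight and the final components
are invariant to how equal-magnitude edges are ordered. The critical weight
reported is that level, i.e. the minimum edge magnitude of the surviving
graph.

Component metrics: order (node count), size (edge count), diameter *d*
(maximum hop count over shortest paths, weights ignored), vanishing point
(maximum edge magnitude — provably the removal level at which the
component's last edge, and with it the component, disappears if the sweep
continues). Major components are those with *d* ≥ `d_min` (default 3,
encoding the strict *d* > 2 rule), sorted by vanishing point descending.
One-edge components are legal throughout the sweep; the diameter filter
applies only at selection time.

## Synthetic study conditions

The two-state trajectory generator plants exact contact-frequency changes.
Pseudo-residues are beads on a straight chain with 20 Å spacing, far beyond
cutoff + maximum probe displacement, so the only inter-residue contacts are
the planted ones. A planted pair (p, q) with multiplicity *m* places *m*
anchor atoms on residue p (one group per pair, groups 4 Å apart, atoms
0.3 Å apart within a group, the first group reusing the Cα) and one probe
atom owned by residue q whose radial distance from the anchor group toggles
between 4.5 Å (contact) and 6.5 Å (no contact) — both far from the 5 Å
boundary, so floating-point cannot flip a contact. Probe directions
alternate sides of the chain; at most three anchor groups fit per residue
before the separation guarantees fail, and the generator rejects such specs
as geometrically infeasible. Contact frames are chosen by a seeded RNG;
with `base_frequency·F` and `(base_frequency+Δ)·F` constrained to integers,
the pipeline recovers every planted weight `Δ·m` exactly (the expected
values are themselves computed from the integer frame counts). Defaults in
tests use F = 20 frames per state, base frequency 0.25 and |Δ| between 0.2
and 0.75 — small enough to exercise fractional averages, large enough that
a planted edge is never ambiguous.

The generator emulates the *statistical* structure of a two-state ensemble
pair — which contacts change and by how much — but none of the physics: no
thermal noise, no correlated motions, no solvent, no conformational
exchange. Passing tests therefore demonstrate that the bookkeeping
(contacts → averaging → projection → subtraction) is exact, not that the
method is robust to sampling noise in real trajectories; on real data the
contact-frequency differences are themselves estimates whose uncertainty
shrinks with trajectory length.

The planted-graph generator wires each cluster (path, cycle, star, or
random-connected topology; analytic diameters n−1, ⌊n/2⌋, 2) at a single
internal magnitude level drawn from `internal_range` and joins consecutive
clusters with bridges drawn from `bridge_range`, requiring
min(internal) > max(bridge). The single level per cluster is what makes
recovery provable: below the smallest cluster level only bridges are
removed, so the level curve peaks at exactly the cluster count with every
cluster intact, and above it each cluster vanishes whole at its own level,
so the count only falls. With per-edge random internal magnitudes a
path-like cluster would shed nodes and split during the sweep, pushing the
maximum count past the planted number — a realistic but no longer
ground-truthed regime, which the unstructured `random_dpcn` generator
covers instead (defaults: 60 nodes, 200 edges, magnitudes 0.05–8).

## Numerical and design choices

- Averages are exact rationals (integer counts / F); the text formats write
  12 significant digits, and round-trip tests compare at 1e-11 relative.
- Trace, graph, matrix and JSON writers sort by residue label, so outputs
  are deterministic; provenance headers (tool version, input hashes,
  cutoff, selection, frame counts, seed) are JSON-encoded comment lines and
  carry no timestamp by default, making re-runs byte-identical.
- The sweep recomputes the BFS component count after every removal rather
  than maintaining an incremental structure; at the graph sizes this
  package targets (10³–10⁴ edges) the quadratic worst case is cheap, and
  the simple form is what the union-find oracle in the tests verifies.
- Problem sizes in the test-suite oracles (100-atom frames, ≤300-edge
  sweeps, ≤5-node exhaustive enumerations, 100 planted trials) were chosen
  so each oracle comparison is exhaustive or statistically dense while the
  whole suite stays interactive.
- `run-all` on two identical ensembles reports an empty perturbation
  network and exits cleanly rather than treating it as an error.

## Known limitations

- No PBC re-imaging, trajectory alignment, or solvent/ligand handling
  beyond atom selection; ligand atoms can be included by a custom selection
  mask but are excluded by default.
- Hop-based diameters only; weighted diameters are not implemented.
- The oscillation fine structure of the count-versus-weight curve between
  the first split and the critical weight can depend on tie order in ways
  the magnitude-level definitions deliberately ignore.
- Viewer export targets PyMOL CGO scripts only.
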
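# morphotree

Branch-level morphometry of digitally reconstructed neurons.

Neuronal reconstructions traced from microscopy are published as SWC
files: a header of `#` comments followed by an *n* × 7 matrix — index,
structure flag (soma / axon / basal / apical dendrite), x, y, z (µm),
radius (µm), parent index.  This "Cartesian" description is complete but
carries little intuitive information.  `morphotree` turns it into
branch-level statistics a neuroanatomist can compare across cells and
cell classes, and can resample those statistics to grow *virtual
neurons* for network simulations.

## What it computes

Every pair of points linked by the parent index is a **segment**; a
**branch** is a maximal chain of segments with one structure flag and no
intervening bifurcation.  Per branch, `morphotree` reports:

* **genealogy** — a unique integer *first-name* plus the *full-name*
  (ancestor list back to the soma); the full-name length is the
  centrifugal order;
* **Strahler order** — terminals are 1; when two daughters of maximal
  order *m* meet, the parent is *m* + 1, otherwise it continues the
  larger order;
* **length** `L = Σ_k |P_k − P_{k−1}|` and Euclidean / path distance to
  the soma;
* **tapering** — OLS slope of diameter (2r) against cumulative arc
  length, plus mean diameter ± SEM;
* **DM tortuosity** — path length over endpoint distance (≥ 1);
* **SOAM tortuosity** — for each interior point, the in-plane angle
  `IP_k = arccos(T̂₁·T̂₂)` and torsional angle
  `TP_k = arccos((T₁×T₂)^·(T₂×T₃)^)` combine into
  `CP_k = √(IP_k² + TP_k²)`; `SOAM = Σ CP_k / L` (rad/µm), so branches
  of different length are comparable;
* **bifurcation angles** — between directional vectors obtained by 3D
  total-least-squares regression over the last/first 5 segments of
  parent and daughter;
* **Rall exponent** — the `E` solving `d_eq^E = Σᵢ dᵢ^E` at each branch
  point (the classic passive-cable prediction is `E = 3/2`).

Populations of cells are summarized as frequency distributions with
Sturges-rule binning (`k = ⌈1 + log₂ n⌉`), mean ± SEM across cells.
A z-axis moving-average filter (arc-length window, boundary-continuous
across bifurcations) removes the digitization noise common in archive
reconstructions.  Finally, per-order empirical distributions can be
refit and resampled into unlimited non-identical virtual neurons,
emitted as valid SWC.

## Worked example

Generate a small synthetic cell and analyze it:

```sh
morphotree fixture --template binary --seed 1 --out cell.swc
morphotree info cell.swc
morphotree strahler cell.swc
morphotree measure cell.swc --out metrics.csv
morphotree bifurcations cell.swc --out bif.csv
```

prints

```
cell.swc: 71 points, 70 segments, 2 header lines, 1 root(s)
  flag 1 (soma): 1 records
  flag 3 (basal dendrite): 70 records
order 1: 4 branches
order 2: 2 branches
order 3: 1 branches
max Strahler order: 3
7 branches -> metrics.csv
3 bifurcations -> bif.csv
```

The cell has 71 points, hence 70 segments — a single-root tree with *n*
points always has *n* − 1 segments.  Its 7 branches form a complete
binary tree of depth 3 (maximum Strahler order 3).  The bifurcation
table shows each branch point's diameters and derived quantities, e.g.

```
x,y,z,parent_branch,d_eq,d_daughters,angles_rad,angles_deg,rall_exponent,rall_failure
3.08333e-15,50.3546,0.0,1,2.0,1.25992;1.25992,1.047197;1.047197,60.0000;60.0000,1.5000024478563705,
```

a parent of diameter 2 µm splitting into two daughters of
2·2^(−2/3) ≈ 1.26 µm at ±60°: the recovered Rall exponent is 3/2 (up to
the 6-digit precision of the SWC file).  The same library API is
available in Python (`read_swc`, `build_forest`, `vertical_compress`,
`fit_morphometry_model`, `generate_virtual_neuron`, …).

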
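# vaspol

Quantitative analysis of endothelial cell polarity against network
hemodynamics, starting from a single binary vessel-lumen mask.

The pipeline:

1. **Network reconstruction** (`vaspol.reconstruct`) — skeletonize the
   mask to a one-pixel centerline, trace it into a spatial graph
   (branch points / endpoints as nodes, ordered pixel paths as edges),
   estimate per-edge radii from the Euclidean distance transform
   (median along the path, −0.5 px center correction), prune short
   terminal spurs, and flag degree-≥4 junctions (the diagnostic for
   vessels that cross at different depths and appear merged in a
   z-projection).
2. **Flow model** (`vaspol.flow`) — 1D Poiseuille network flow:
   Kirchhoff node balance with edge conductance g = πr⁴/(8 μ_eff L)
   under pressure boundary conditions, with either Newtonian or
   Carreau–Yasuda shear-thinning rheology (effective viscosity updated
   by a relaxed fixed-point loop).  Outputs node pressures, signed edge
   flows, velocities, wall shear rates, WSS magnitudes, and oriented
   WSS vectors sampled along every centerline.
3. **Polarity** (`vaspol.polarity`) — nucleus→Golgi polarity vectors
   from a point-pair CSV, matched to the nearest perfused centerline
   WSS sample; signed relative angle θ (from WSS vector to polarity
   vector, counterclockwise positive, (−180°, 180°]), scalar product
   p·t, optional region labels from polygons.
4. **Statistics** (`vaspol.stats`) — four analyses: a directionality
   table (fraction of cells polarized against flow, i.e. within
   180°±45°), polar histograms with Kuiper uniformity and two-sample
   tests (plus a Rayleigh test as a labeled secondary), a WSS
   sensor-threshold curve (against-flow fraction per WSS quantile bin,
   threshold at the 60% crossing), and scalar-product slope regressions
   per sign subgroup.
5. **Synthetic fixtures** (`vaspol.fixtures`) — ideal tube / crossing /
   vein-artery-vein plexus masks and cell populations with von Mises
   polarity coupled to local WSS, so every test and demo runs without
   external data.

## A note on the flow solver

The reduced 1D network model deliberately replaces a resolved 3D
lattice-Boltzmann simulation.  It preserves the boundary-condition
design (pressure BCs at network inlets/outlets in a vein–artery–vein
configuration) and the output quantities (pressure, velocity, shear
rate, oriented WSS vectors), which are all the downstream polarity
analyses consume.  It does not capture plasma skimming, the
Fåhræus–Lindqvist effect, pulsatility, or non-circular lumen
cross-sections.

The default Carreau–Yasuda parameters in `examples/config.toml` are
generic literature whole-blood values and are configuration, not
constants.

## CLI

```sh
# generate a synthetic plexus and run everything on it
vaspol run --fixture-vav --n-cells 400 --seed 0 --out results/demo

# or stage by stage on your own data
vaspol build-network mask.png --pixel-size-um 0.62 --out results/net
vaspol solve-flow results/net.graphml --config examples/config.toml --out results/flow
vaspol attach-flow cells.csv results/net.graphml results/flow_wss_samples.csv \
    --pixel-size-um 0.62 --out results/cells_with_flow.csv
vaspol analyze results/cells_with_flow.csv --out results/analysis

# synthetic fixtures
vaspol make-fixture tube --out scratch/tube
vaspol make-fixture crossing --out scratch/x
vaspol make-fixture cells --n-cells 300 --out scratch/demo
```

`vaspol run` writes a full bundle: GraphML + CSV network tables, flow
and WSS-sample CSVs, the cells-with-flow table, the four analysis
outputs, six figures (overlay, polar histogram, sensor curve, slope
scatter, caliber and WSS histograms), `results.json`, and a
`manifest.json` from which the run can be reproduced bit-identically
(`--config manifest.json`).

Cell input CSV columns: `cell_id, nucleus_x, nucleus_y, golgi_x,
golgi_y` (pixel coordinates).  Region polygons: CSV with `label, x, y`
vertex rows (micrometres).

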
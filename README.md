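# wavefc

Frequency-resolved ("multispectral") functional connectivity analysis of
BOLD-fMRI voxel time series via the wavelet packet transform.

Resting-state functional connectivity (FC) is usually computed from
band-passed low-frequency fluctuations (0.01–0.1 Hz), yet BOLD signals carry
1/f-type power (S(f) ∝ 1/f^γ, γ ≈ 0.5–1) across a much wider range, and
network structure need not be the same in every band.  `wavefc` implements a
pipeline for asking how FC networks change across frequency:

1. **Wavelet packet transform (WPT).**  Each voxel series is recursively
   split with the Daubechies 7-vanishing-moment quadrature-mirror filter
   pair into a full packet tree over depths 0–6 (127 subbands).  Packet
   `DdPp` covers roughly `[p, p+1]·(fs/2)/2^d` Hz, with positions exposed in
   frequency (Gray-code/sequency) order.
2. **Per-subband connectivity.**  For one packet, coefficients are
   concatenated voxel-by-voxel across subjects and FC is the Pearson
   correlation distance `S1 = 1 − r` between voxel rows.
3. **Hierarchical clustering.**  Average linkage
   `S2(a,b) = (1/n_a n_b) ΣΣ S1(i∈a, j∈b)` builds a dendrogram per subband;
   flat parcellations come from requesting `k` clusters or from pruning
   links whose inconsistency `Y4(k) = (z(k) − Y1(k))/Y2(k)` (a z-score of a
   link's height against the links beneath it, within a window of `g`
   dendrogram levels, or the whole subtree for `g = "global"`) exceeds a
   threshold.
4. **Partition comparison.**  Subband parcellations are compared with the
   variation of information
   `VI(C′,C″) = [H(C′) − I(C′,C″)] + [H(C″) − I(C′,C″)]` (bits), a true
   metric between partitions; the packet-by-packet VI matrix is itself
   clustered ("meta-clustering") to reveal how networks segment across
   passbands.
5. **Voxelwise comparison.**  For each voxel, the top-5% correlation
   neighbor set in one subband is compared by Jaccard distance
   `JD = |v Δ w| / |v ∪ w|` to the same voxel's neighbors in a *wideband*
   signal — the inverse WPT keeping only six packets
   (D6P1, D5P1, D4P1, D5P4, D5P5, D4P3 ≈ 12–194 mHz) — averaged across
   subjects.

Because suitable public data require heavy preprocessing, the package ships
a first-class synthetic-data module: multi-subject BOLD-like datasets with
per-voxel 1/f^γ backgrounds and *planted layers* (a ground-truth
parcellation active only inside a chosen passband), so every stage is
testable end-to-end against a known answer.

## Worked example

Plant two independent 6-cluster parcellations — layer A active in
24–48 mHz, layer B in 121–194 mHz, both at amplitude 2 relative to the 1/f
background — and recover them from the matching packets:

```python
import wavefc as w

cfg = w.default_two_layer_config(n_voxels=300, n_subjects=3, seed=7)
datasets, truth = w.synthesize_dataset(cfg)
trees = [w.wpt_decompose(d.data, max_depth=6, fs=d.fs) for d in datasets]

def parcellate(name):
    group = w.concatenate_group([t.node(name) for t in trees])
    dist = w.correlation_distance(group)
    return w.prune_to_k(w.average_linkage(dist), 6)

low  = parcellate("D5P1")   # 24-48 mHz packet
high = parcellate("D4P3")   # 145-194 mHz packet
print("VI(D5P1, layer A) = %.3f bits" % w.variation_of_information(low,  truth.partition(0)))
print("VI(D5P1, layer B) = %.3f bits" % w.variation_of_information(low,  truth.partition(1)))
print("VI(D4P3, layer B) = %.3f bits" % w.variation_of_information(high, truth.partition(1)))
```

prints

```
VI(D5P1, layer A) = 0.000 bits
VI(D5P1, layer B) = 5.017 bits
VI(D4P3, layer B) = 0.000 bits
```

i.e. the packet inside each planted band recovers its own layer's
parcellation exactly (VI = 0) while carrying essentially no information
about the other layer (VI near its ~5.2-bit ceiling for these partitions).

The same pipeline is scriptable from the shell:

```bash
wavefc run --config pipeline.yaml --seed 0 --out my-run
# or stage by stage:
wavefc simulate --config pipeline.yaml
wavefc decompose --config pipeline.yaml
wavefc connectivity --config pipeline.yaml
wavefc cluster --config pipeline.yaml --k 6
wavefc compare --config pipeline.yaml --mode coarse-local
wavefc voxelmap --config pipeline.yaml
```

Each stage writes NIfTI/HDF5/CSV artifacts plus JSON sidecars under the
output directory, and `run` records a `manifest.json` with parameters,
seeds and content hashes; unchanged stages are skipped on re-runs.

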
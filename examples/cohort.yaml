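# small synthetic cohort: 6 healthy + 3 CSC eyes on a fast 64 x 64 grid
n_healthy: 6
n_csc: 3
effect: 8.2        # CSC CVD offset at equal SCT, percentage points
slope: 3.9         # CVD points per 100 um of SCT
grid: 64
seed: 2
artefact_fraction: 0.1
write_maps: true
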
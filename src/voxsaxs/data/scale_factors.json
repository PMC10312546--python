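{
 "comment": "Per-element excluded-volume scale factors correcting for solvent-inaccessible voids. Identity defaults; recalibrate against a high-quality benchmark profile with voxsaxs.volumes.calibrate_scale_factors (bulk density pinned at 0.334 e-/A^3).",
 "version": 1,
 "factors": {"H": 1.0, "C": 1.0, "N": 1.0, "O": 1.0}
}
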
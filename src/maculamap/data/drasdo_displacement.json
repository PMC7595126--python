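{
  "comment": "Monotone lookup from stimulus (photoreceptor) eccentricity to ganglion-cell eccentricity, in visual degrees along the same meridian. Digitized from the published ganglion-cell displacement curve (Henle fibre elongation); identity beyond the cutoff. Values are a smooth plausible digitization; analyses depending on them must only rely on monotonicity and centrifugality.",
  "stimulus_ecc_deg": [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0],
  "gc_ecc_deg":       [0.0, 1.8, 2.4, 2.9, 3.2, 3.45, 3.7, 4.35, 5.3, 6.3, 7.3, 8.2, 9.1, 10.03, 11.0, 12.0],
  "cutoff_deg": 12.0
}
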
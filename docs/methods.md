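# Methods

## The quantitation model

A cross-linked peptide pair carrying an isotope-coded cross-linker gives
two MS1 isotope clusters ("partners") separated by
`Δ(m/z) = label_count × label_mass / z`. The light partner's isotope peak
k sits at `mz0 + k·1.0033548378/z` (13C–12C spacing), the heavy partner's
at the same offsets above `mz0 + Δ`. For every PSM the algorithm:

1. resolves the elution time `t_MS2` from the identifying MS2 scan header;
2. builds per-partner integration windows
   `[t_MS2 − w, t_MS2 + w]` (w = the ID list's `quant_window` half-width),
   extending the window of the partner not matching the PSM's
   `label_state` by `extension_seconds` — towards earlier times for the
   heavy partner, later times for the light one. Deuterated peptides bind
   slightly less to reversed-phase material and elute earlier, so the MS2
   anchor taken on one partner can miss the other partner's peak entirely
   without this extension;
3. extracts XICs (±`tolerance_ppm`) for isotope peaks 1–3 of each partner,
   one point per MS1 scan, explicit zeros for scans without a match;
4. sums the three traces of a partner, locates the apex (maximum
   intensity, earliest retention time on ties), and extends boundaries in
   both directions over the contiguous points with intensity
   ≥ `boundary_fraction` × apex; the first point below the threshold is
   excluded, and a boundary that reaches the window edge sets a
   `truncated` flag. The area is the trapezoidal integral between the
   boundaries;
5. reports `ratio_hl = heavy_area / light_area`, withheld (with a
   `light_missing`/`heavy_missing` flag) whenever either area is zero —
   never reported as 0 or infinity.

Site-level ratios are the median over all supporting PSM ratios (ratio
scale; even counts: mean of the two central values — by monotonicity of
log2 this equals the median of the log2 ratios). Sites with fewer than
`min_evidence` (default 2) defined ratios go to a separate
insufficient-evidence listing. Replicate agreement is scored on the log2
medians of the sites observed in both runs: Pearson r, RMSE, and r² as
the coefficient of determination.

### Why isotope peaks 1–3 and not the monoisotopic peak

The label spacing (~4.025 Da) is close to, but not exactly, four isotope
spacings (4.013 Da). For cross-linked peptide pairs (typically
1500–5000 Da) the monoisotopic peak is small relative to the cluster
maximum, and the 4th/5th isotope of the light cluster can fall within a
few ppm of the heavy cluster's first peaks. Excluding isotope 0 removes
the worst overlap (light isotope 4 → heavy isotope 0) at negligible cost
in signal. The residual overlap (light isotope 5 → heavy isotope 1 at
charge 3) is accepted, matching practice; at 1:1 mixing it contributes
the small positive bias (~+0.06 log2 units) visible in the acceptance
numbers.

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `tolerance_ppm` | 6 | ppm | MS1 accuracy the identifications were searched with |
| `isotope_spacing_da` | 1.0033548378 | Da | 13C–12C mass difference |
| `label_mass` | 4.0251056 | Da | 4 × (2H–1H); the nominal 4.0 would mis-target peaks at high charge under a tight ppm tolerance |
| `boundary_fraction` | 0.10 | — | 10 %-of-apex elution-peak boundary rule |
| `extension_seconds` | = quant_window | s | the deuterium shift can reach a substantial fraction of the peak width; one extra half-width is a safe envelope |
| `apex_mode` | `summed` | — | one apex per partner on the summed isotope-1..3 trace; prevents the three isotopes locking onto different co-eluting species (`per_isotope` gives the strict independent-trace behaviour) |
| `min_evidence` | 2 | PSMs | "at least two" supporting evidences per reported site |

## The synthetic-data generator

`synth.default_design` emulates one benchmark acquisition: `n_doublets`
cross-linked peptide pairs sharing one true heavy:light mixing ratio
(benchmark: 1:1, 1:2, 1:4 in triplicate), masses uniform in 1500–5000 Da,
charges 3–5 (1+/2+ precursors are not selected for fragmentation in such
experiments), Gaussian elution (σ 5–8 s) on a 2 s MS1 grid over a 900 s
span, apex intensities log-normal around 10⁶. The heavy partner is the
light one scaled by the true ratio and shifted by N(−15, 5) s (the
deuterium isotope effect; both small- and large-shift regimes can be
generated via `heavy_rt_shift_mean/sd`). Noise: multiplicative log-normal
intensity scatter (CV 0.15) per peak, 2 ppm Gaussian m/z jitter, and
Poisson chemical noise (5 peaks per scan per 100 Th, exponential
intensities at a floor of 30). One MS2 header per doublet is placed just
after the MS1 scan nearest the light apex; MS2 spectra carry no fragment
peaks because only the header time is used. All randomness flows from a
single seed; identical seeds give byte-identical mzML files.

Both partners share one averagine isotope envelope (elemental composition
scaled from C4.9384 H7.7583 N1.3577 O1.4773 S0.0417 per 111.1254 Da,
elemental distributions convolved by exponentiation-by-squaring). The d4
label's real effect on the envelope is below everything this generator is
used to test and ignoring it makes noiseless ground truth exact.

What the generator does *not* emulate: chromatographic tailing,
co-eluting near-isobaric peptides, dynamic exclusion, detector
saturation, and between-run retention drift. A green recovery test
therefore establishes correctness of the doublet arithmetic, windowing,
integration and aggregation — not robustness to every pathology of real
chromatography.

## Numerical choices and edge cases

- Apex ties break to the earliest retention time (deterministic output).
- Boundary points strictly below the threshold are excluded; no sub-scan
  interpolation of the 10 % crossing.
- Multiple centroid peaks inside the m/z tolerance of one scan are summed
  (robust to centroid splitting; `xic_combine = max` selects the most
  intense instead).
- Retention times are converted to seconds at the mzML reader boundary,
  whatever unit the file declares.
- Exact m/z ties within one scan are merged by intensity summation at
  load time.
- Windows with no MS1 scans yield empty traces → missing-partner flags,
  not exceptions; a missing MS2 header flags that PSM and processing
  continues.
- In noiseless designs the heavy retention shift is snapped to the scan
  grid so that both partners sample identical profile values and ratio
  recovery is exact to float precision.

## Known limitations

- No correction for the residual light-into-heavy isotope-cluster
  overlap (see above); heavy ratios are slightly inflated at high m/z and
  charge 3.
- No retention-time alignment or normalisation across runs; replicate
  comparison assumes the same site keys mean the same species.
- mzML support covers centroided MS1 + MS2 headers (64/32-bit floats,
  zlib or uncompressed); profile data must be centroided upstream.
- One ratio per PSM; no significance testing between conditions.
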
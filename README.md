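# civetniche

Spatial, temporal and dietary niche-overlap analysis for pairs of sympatric
carnivores, from camera-trap detections and scat contents. The worked example
throughout is the civet pair of the Himalayan foothills — the Asian palm civet
(*Paradoxurus hermaphroditus*, 108 scats, 98 detections) and the small Indian
civet (*Viverricula indica*, 44 scats, 1,321 detections) — whose published
diet composition table ships with the package.

The package is for field ecologists who have (a) a camera-trap detection log
(site, species, date, time) and/or (b) per-scat food-item records, and want
the standard niche-partitioning statistics with a verifiable, scriptable
implementation.

## The statistics

**Space.** Each species' use of space is its vector of per-site detection
shares *p*<sub>ij</sub> (independent detections of species *j* at site *i*
over its total). Overlap is Pianka's index

O<sub>jk</sub> = Σ<sub>i</sub> p<sub>ij</sub> p<sub>ik</sub> / √(Σ p<sub>ij</sub>² · Σ p<sub>ik</sub>²) ∈ [0, 1].

Detections are first thinned with a greedy 30-minute independence filter per
(site, species): an event is kept iff it falls ≥ 30 min after the last kept
event of its group.

**Time.** Capture times are mapped to the circle (24 h → 2π) and each
species' diel activity density is a von Mises kernel density estimate whose
concentration comes from Taylor's plug-in rule
κ_bw = [3n κ̂² I₂(2κ̂) / (4√π I₀(κ̂)²)]^{2/5}, with κ̂ the ML von Mises
concentration (A(κ̂) = R̄). The coefficient of overlapping
Δ = ∫ min(f, g) is estimated either by trapezoid integration of
min(f̂, ĝ) (Δ̂1) or by averaged bounded density ratios at the observed points
(Δ̂4, preferred when both n > 75), and classified low (≤ 0.50), moderate
(0.50–0.75] or high (> 0.75).

**Diet.** From frequency of occurrence FO (number of scats containing an
item): RFO = 100·FO/ΣFO, Levins breadth L = 1/Σp², standardised breadth
Lst = (L−1)/(n−1), Shannon diversity H′ = −Σ p ln p, Pielou evenness
E = H′/ln S, richness S, and the dietary Pianka overlap on the two RFO
proportion vectors.

A synthetic-data module generates detections (multinomial site preference ×
von Mises-mixture activity) and scats with *known ground truth*, including a
quadrature oracle for the true Δ of two activity models and an exact-replay
mode that turns an FO column back into individual scats — so every estimator
is testable end to end without any external data.

## Worked example

The dietary analysis of the packaged composition table:

```sh
python analysis/04_dietary_metrics.py
```

prints

```
33 item categories; total occurrences 193 (palm civet, 108 scats) and 62 (small Indian civet, 44 scats)
asian_palm_civet: S = 29, H' = 2.78, E = 0.83, L = 9.30, Lst = 0.30
small_indian_civet: S = 19, H' = 2.53, E = 0.86, L = 8.86, Lst = 0.44
group RFO subtotals (asian_palm_civet): {'wild animal': 33.7, 'domestic animal': 10.9, 'plant': 53.4, 'other': 2.1}
group RFO subtotals (small_indian_civet): {'wild animal': 30.6, 'domestic animal': 14.5, 'plant': 51.6, 'other': 3.2}
dietary Pianka overlap: 0.9031 (high: both civets rely on the same orchard fruits and rodents)
```

Both species eat a wide range of items (richness 29 and 19, diversity 2.78
and 2.53 nats) dominated by the same few — wild Himalayan pear (27.5% vs
24.2% of occurrences), rodents and poultry — hence the high dietary overlap
of 0.90. The companion scripts `analysis/01–03` simulate a study-scale
camera-trap dataset with known truth and run the spatial and temporal stages
on it; `civetniche all <config.yaml>` runs everything from a YAML config, and
`civetniche diet|spatial|temporal|simulate|fixtures` expose the stages
individually.

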
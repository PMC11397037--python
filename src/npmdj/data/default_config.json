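{
  "model_version": "NPM-DJ-1.0",
  "energy_reference_kcal": 2200,
  "sodium_reference_mg": 2756,
  "salt_target_g": 7.0,
  "protein_nrv_g": 81,
  "fiber_nrv_g": 19,
  "band_start_fraction": 0.0375,
  "satfat_energy_fraction": 0.07,
  "sugars_energy_fraction": 0.10,
  "satfat_kcal_per_g": 9.0,
  "sugars_kcal_per_g": 4.0,
  "fvnl_zero_below_fraction": 0.40,
  "cap_baseline_threshold": 13,
  "cap_v_exemption": 5,
  "bands": {
    "energy": {
      "unit": "kcal",
      "mode": "linear",
      "width": 82.5,
      "max_points": 9,
      "provenance": "anchored",
      "note": "first band opens at 3.75% of the 2200 kcal labeling reference; equal widths thereafter"
    },
    "satfat": {
      "unit": "g",
      "mode": "energy_linear",
      "energy_fraction": 0.07,
      "kcal_per_g": 9.0,
      "max_points": 17,
      "provenance": "reconstructed",
      "note": "band anchor at saturated fat supplying 7% of the dish's energy; interior widths reconstructed as equal"
    },
    "sugars": {
      "unit": "g",
      "mode": "energy_linear",
      "energy_fraction": 0.10,
      "kcal_per_g": 4.0,
      "max_points": 10,
      "provenance": "reconstructed",
      "note": "band anchor at total sugars supplying 10% of the dish's energy; interior widths reconstructed as equal"
    },
    "sodium": {
      "unit": "mg",
      "mode": "linear",
      "width": 103.35,
      "max_points": 30,
      "provenance": "anchored",
      "note": "first band opens at 3.75% of 2756 mg sodium (the 7 g salt intake target); equal widths thereafter"
    },
    "v": {
      "unit": "fraction",
      "mode": "span",
      "start": 0.40,
      "stop": 1.00,
      "max_points": 8,
      "provenance": "reconstructed",
      "note": "eight thresholds evenly spaced from 0.40 to 1.00; fvnl of exactly 100% scores 7, the eighth point opens only above 100% (concentrated inputs)"
    },
    "protein": {
      "unit": "g",
      "mode": "linear",
      "width": 3.0375,
      "max_points": 15,
      "provenance": "reconstructed",
      "note": "band anchor at 3.75% of the 81 g protein NRV; published description adjusts points 2-15 by a weighted average with the HSR scale, reconstructed here as equal widths"
    },
    "fiber": {
      "unit": "g",
      "mode": "linear",
      "width": 0.7125,
      "max_points": 15,
      "provenance": "reconstructed",
      "note": "band anchor at 3.75% of the 19 g fiber NRV; the published description states the linear stretch as 1-5 points in one passage and 2-5 in the next (contradiction left unresolved), with 6-15 adjusted against the HSR scale; reconstructed here as equal widths throughout"
    }
  }
}
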
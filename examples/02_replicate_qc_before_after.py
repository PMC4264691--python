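"""Biological-replicate %CV before vs after normalization.

Simulates a triplicated 100-condition study (10% true biological
replicate CV) on a slide with smooth spatial bias, then compares the
slide-mean %CV of the replicate groups before and after correction
against the conventional 15% slide-acceptance cutoff.
"""

from rppanorm import (
    SimulationConfig, build_default_layout, compare_before_after,
    low_freq_sinusoid, normalize_slide, simulate_replicate_study,
)

layout = build_default_layout()
config = SimulationConfig(layout=layout, noise_sigma_log=0.05,
                          bias=low_freq_sinusoid(layout, amplitude=0.3))
slide, truth, grouping = simulate_replicate_study(
    config, n_conditions=100, n_bio_replicates=3, replicate_cv=0.10, seed=2)

report = compare_before_after(slide, normalize_slide(slide), grouping)
print(f"slide-mean %CV before: {report.before.mean_cv:.2f}%  "
      f"(pass at 15%: {report.before.passed})")
print(f"slide-mean %CV after:  {report.after.mean_cv:.2f}%  "
      f"(pass at 15%: {report.after.passed})")
print(f"Z'-factor before/after: {report.z_prime_before:.3f} / "
      f"{report.z_prime_after:.3f}")
# Spatial bias inflates the apparent replicate CV well above the true 10%;
# correction brings it back near the truth, here rescuing the slide at the
# 15% cutoff, and sharpens positive/negative control separation (Z').
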
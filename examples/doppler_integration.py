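"""Recover compression depth by integrating the micro-Doppler envelope.

For each target depth the envelope of the spectrogram is detected at the
maximal energy derivative, segmented into compression cycles, and
integrated: d = (lambda / 2) * int |f| dt.  Noise-free, frontal geometry;
the recovered means should sit within a few percent of the target.
"""

from mdcpr import (
    CompressionScenario,
    RadarConfig,
    SubjectProfile,
    estimate_depths,
    phase_synthesize,
    project_radial,
    simulate_kinematics,
)

config = RadarConfig()
clean = SubjectProfile(0.0, 0.0, 0.0)

print("target depth -> estimated depth (mean over cycles)")
for depth_cm in (3.0, 4.0, 5.0, 6.0):
    scenario = CompressionScenario(
        target_depth_cm=depth_cm, rate_cpm=100.0, duration_s=10.0,
        subject_profile=clean, noise_snr_db=None,
    )
    trace = simulate_kinematics(scenario, config)
    signal = phase_synthesize(trace, config)
    cycles = estimate_depths(signal)
    est = cycles["depth_cm"].mean()
    print(f"  {depth_cm:.0f} cm -> {est:5.2f} cm  ({len(cycles)} cycles, "
          f"error {100 * (est - depth_cm) / depth_cm:+.1f}%)")

# oblique geometry: the radar sees only d cos(theta); compensation divides
theta = 45.0
scenario = CompressionScenario(
    target_depth_cm=5.0, rate_cpm=100.0, duration_s=10.0,
    aspect_angle_deg=theta, subject_profile=clean, noise_snr_db=None,
)
trace = simulate_kinematics(scenario, config)
radial = project_radial(trace, theta)
signal = phase_synthesize(radial, config)
est = estimate_depths(signal, aspect_angle_deg=theta)["depth_cm"].mean()
print(f"aspect angle {theta:.0f} deg, 5 cm target -> {est:.2f} cm after compensation")
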
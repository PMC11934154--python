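"""Generate a synthetic spheroid and map its per-pixel dynamics.

Builds a 128x128 phantom (viable shell fluctuating in 8-9.5 Hz,
necrotic core in 11.5-13 Hz), computes the Welch-PSD centroid
frequency map, and compares the measured per-layer means with the
generator's analytic expectations.
"""

from doct import PhantomSpec, WelchParams, compute_dynamics_maps, generate_phantom

spec = PhantomSpec(
    shape=(128, 128),
    outer_radii=(140.0, 140.0),  # um
    core_radii=(70.0, 70.0),
    n_frames=256,
    seed=1,
)
stack, labels, expected = generate_phantom(spec)
maps = compute_dynamics_maps(stack, WelchParams(segment_length=128))

print(f"stack shape (time, z, x): {stack.shape}")
for label, name in ((1, "viable shell"), (2, "necrotic core")):
    measured = maps.fmean[labels == label].mean()
    print(
        f"{name:14s} fmean: measured {measured:5.2f} Hz, "
        f"analytic {expected[name.split()[0]]:5.2f} Hz"
    )
# The viable shell sits near the 8-9.5 Hz band midpoint and the core near
# the 11.5-13 Hz midpoint: the frequency contrast the method segments on.
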
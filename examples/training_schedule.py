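"""Training-configuration arithmetic: epochs, LR decay, init limits.

These are the deterministic numbers a detector configuration is built
from; no network is constructed here.
"""

from lesionprep import ScheduleParams, cosine_lr, epochs, init_limit

params = ScheduleParams(total_steps=200_000, batch_size=32,
                        train_set_size=39_592, base_lr=0.05)
e = epochs(params)
print(f"{params.total_steps:,} steps x batch {params.batch_size} over "
      f"{params.train_set_size:,} images = {e:.2f} epochs (~{round(e)})")

print("\ncosine learning-rate decay (no warmup):")
for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
    step = int(frac * params.total_steps)
    print(f"  step {step:>7,}: lr = {cosine_lr(step, params.total_steps):.5f}")

print("\nuniform init limit sqrt(3/fan_in):")
for n in (3, 12, 1024):
    print(f"  fan-in {n:>5}: weights ~ U(-{init_limit(n):.4f}, +{init_limit(n):.4f})")
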
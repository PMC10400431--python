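"""Independent brute-force oracles used by several test modules."""

import numpy as np

REST_SPEED = 0.02
REST_ACCEL = 0.2
MOVE_SPEED = 0.03


def classify_frames_oracle(speed, accel, sample_rate):
    """Direct rule evaluation frame by frame, then bout resolution.

    Written independently of the package implementation: explicit loops,
    no run-length machinery.
    """
    n = len(speed)
    lab = []
    for i in range(n):
        if speed[i] < REST_SPEED and abs(accel[i]) < REST_ACCEL:
            lab.append("rest")
        elif speed[i] > MOVE_SPEED:
            lab.append("movement")
        else:
            lab.append(None)
    short = int(np.ceil(1.0 * sample_rate))
    i = 0
    out = list(lab)
    while i < n:
        if out[i] is not None:
            i += 1
            continue
        j = i
        while j < n and out[j] is None:
            j += 1
        left = out[i - 1] if i > 0 else None
        right = lab[j] if j < n else None
        if left is None and right is None:
            fill = "rest"
        elif left is None:
            fill = right
        elif right is None:
            fill = left
        elif left == "rest" and right == "rest":
            fill = "rest"  # < 1 s by the stated rule; >= 1 s never crossed threshold
        else:
            fill = "movement"
        for k in range(i, j):
            out[k] = fill
        i = j
    return np.asarray(out)


def random_toy_trace(rng, n=300, sample_rate=100.0):
    """A random kinematic profile exercising all three frame categories."""
    speed = np.abs(rng.normal(0.025, 0.02, n))
    # inject runs of clear rest and clear movement
    for _ in range(rng.integers(1, 4)):
        a = rng.integers(0, n - 20)
        speed[a : a + rng.integers(5, 20)] = rng.uniform(0.0, 0.015)
    for _ in range(rng.integers(1, 4)):
        a = rng.integers(0, n - 20)
        speed[a : a + rng.integers(5, 20)] = rng.uniform(0.04, 0.1)
    accel = rng.normal(0.0, 0.3, n)
    return speed, accel
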
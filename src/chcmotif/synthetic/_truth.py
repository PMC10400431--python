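"""Ground-truth container shared by the three generators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GroundTruth:
    """Known generative state of a simulated dataset.

    Only the fields relevant to the generator that produced it are filled;
    the rest stay None.
    """

    # behavior
    frame_state_true: np.ndarray | None = None  # 'rest'/'movement' per frame
    md_true: np.ndarray | None = None  # degrees, NaN at rest
    goal_center_xy: tuple | None = None  # maze coords of the goal center
    reward_times_true: np.ndarray | None = None

    # population
    events_true: np.ndarray | None = None  # binary raster neurons x frames
    pd_true: np.ndarray | None = None
    kappa_true: np.ndarray | None = None
    dff_true: np.ndarray | None = None  # noiseless kernel-convolved raster

    # synapse stack
    ais_geometry_true: list = field(default_factory=list)
    pre_sse_true: np.ndarray | None = None
    post_sse_true: np.ndarray | None = None
    puncta_true: list = field(default_factory=list)
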
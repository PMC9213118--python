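"""LRAA: two-stage learning-rate annealing for Adam.

The schedule keeps the learning rate constant for the first half of training
(epochs < tau = s // 2, s the planned epoch count) and thereafter monitors
the loss of adjacent epochs: whenever an epoch fails to improve on the
previous one, the rate is halved, floored at ``lr_floor``.  The rate never
increases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class LRAAState:
    """Mutable schedule state.

    lr: current learning rate (eta); total_epochs: planned epoch count (s);
    decay_start: epoch at which annealing begins (tau = s // 2); epoch: number
    of completed epochs; prev_loss: loss of the previous epoch, if any.
    """

    lr: float = 1e-4
    total_epochs: int = 150
    decay_start: int = field(default=None)  # type: ignore[assignment]
    epoch: int = 0
    prev_loss: float | None = None
    lr_floor: float = 1e-6

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.lr_floor <= 0 or self.lr_floor > self.lr:
            raise ValueError("lr_floor must be in (0, lr]")
        if self.total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")
        if self.decay_start is None:
            self.decay_start = self.total_epochs // 2


def lraa_step(state: LRAAState, epoch_loss: float) -> LRAAState:
    """Advance the schedule by one completed epoch.

    Stage 1 (epoch < decay_start): the rate is untouched.  Stage 2: if the
    epoch's loss did not improve on the previous epoch's, the rate is halved
    (never below ``lr_floor``).  Returns a new state; the input is unchanged.
    """
    if not math.isfinite(epoch_loss):
        raise ValueError(f"epoch loss must be finite, got {epoch_loss}")
    lr = state.lr
    if state.epoch >= state.decay_start and state.prev_loss is not None:
        if epoch_loss >= state.prev_loss:
            lr = max(lr / 2.0, state.lr_floor)
    return LRAAState(lr=lr, total_epochs=state.total_epochs,
                     decay_start=state.decay_start, epoch=state.epoch + 1,
                     prev_loss=epoch_loss, lr_floor=state.lr_floor)
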
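"""Gradient x input relevance maps for the TAC classifiers.

First-order Taylor attribution: the relevance of input cell x[g, t] is
``d f_target / d x[g, t] * x[g, t]`` where ``f_target`` is the pre-softmax
logit of the target class (post-softmax gradients saturate once the model is
confident; the logit target is configurable). The gradient is exact, computed
by the same reverse-mode machinery that trains the model, and relevance is
evaluated on the min-max-scaled inputs — the features the network actually
sees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, log_softmax
from .datatypes import FeatureSet
from .features import minmax_apply
from .model import TrainedModel

__all__ = ["RelevanceMap", "taylor_relevance", "relevance_maps", "mean_composite"]

CLASS_INDEX = {"CN": 0, "AD": 1}


@dataclass
class RelevanceMap:
    """Per-cell relevance, same shape as the subject's TAC (regions x frames)."""

    values: np.ndarray
    subject_id: str
    target: str

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("relevance map contains non-finite values")


def _target_scalar(logits: Tensor, target: str, i: int) -> Tensor:
    if target in CLASS_INDEX:
        return logits[i, CLASS_INDEX[target]]
    if target == "prob_AD":
        return log_softmax(logits, axis=1).exp()[i, 1]
    raise ValueError("target must be 'CN', 'AD' or 'prob_AD'")


def taylor_relevance(model: TrainedModel, fs: FeatureSet, target: str = "AD") -> list[RelevanceMap]:
    """Gradient x input relevance of each subject's TAC for the target class.

    Works for any model that consumes the TAC (early-only or dual-phase).
    Subjects are processed one at a time so each backward pass attributes a
    single scalar; inference is deterministic, so maps are batch-independent.
    """
    if model.phase == "delay":
        raise ValueError("the delay-only model does not consume TAC input")
    model.net.eval()
    scaled = minmax_apply(model.mm_tac, fs.tac.reshape(len(fs), -1)).reshape(fs.tac.shape)
    suvr_scaled = None
    if model.phase == "dual":
        suvr_scaled = minmax_apply(model.mm_suvr, fs.suvr)
    maps = []
    for i in range(len(fs)):
        steps = [
            Tensor(scaled[i : i + 1, :, t], requires_grad=True)
            for t in range(scaled.shape[2])
        ]
        sv = None if suvr_scaled is None else Tensor(suvr_scaled[i : i + 1])
        logits = model.net(steps, sv)
        _target_scalar(logits, target, 0).backward()
        grad = np.stack([s.grad[0] for s in steps], axis=1)  # (regions, frames)
        maps.append(
            RelevanceMap(values=grad * scaled[i], subject_id=fs.ids[i], target=target)
        )
    return maps


relevance_maps = taylor_relevance


def mean_composite(maps: list[RelevanceMap], axis: str = "over_regions") -> np.ndarray:
    """Average maps across subjects, then across the stated axis.

    ``over_regions`` yields a per-frame profile (the mean composite relevance
    along the time axis); ``over_time`` a per-region profile.
    """
    if not maps:
        raise ValueError("empty map list")
    shapes = {m.values.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError("maps have differing shapes")
    stack = np.stack([m.values for m in maps])
    mean_map = stack.mean(axis=0)
    if axis == "over_regions":
        return mean_map.mean(axis=0)
    if axis == "over_time":
        return mean_map.mean(axis=1)
    raise ValueError("axis must be 'over_regions' or 'over_time'")
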
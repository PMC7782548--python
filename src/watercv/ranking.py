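"""Derivative-based relevance ranking of descriptors in a trained CV.

The relevance of descriptor i in a metastable state is the state average of
the absolute input gradient of the biased CV,

    weight_i = < |d s_w / d d_i| >_state ,

normalised to sum to 1. Computed per state (bound vs unbound), it shows
which water descriptors the CV actually drives in each state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .deeplda import DeepLDAModel


def descriptor_relevance(
    model: DeepLDAModel,
    samples: np.ndarray,
    normalize: str = "sum",
    use_stretch: bool = True,
) -> np.ndarray:
    """Mean absolute gradient of the CV per descriptor over the samples.

    ``normalize``: "sum" (weights sum to 1), "max" (largest weight 1) or
    "none". ``use_stretch=False`` ranks the raw projection s instead of s_w.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 1:
        raise ValueError("need at least one sample")
    if samples.shape[1] != model.n_descriptors:
        raise ValueError(
            f"samples have {samples.shape[1]} descriptors, model expects "
            f"{model.n_descriptors}"
        )
    if use_stretch:
        grads = model.cv_gradient(samples)
    else:
        x = (samples - model.input_mean) / model.input_std
        grads = model.net.input_gradient(x, model.w) / model.input_std
    w = np.mean(np.abs(grads), axis=0)
    if normalize == "sum":
        total = w.sum()
        return w / total if total > 0 else w
    if normalize == "max":
        top = w.max()
        return w / top if top > 0 else w
    if normalize == "none":
        return w
    raise ValueError(f"unknown normalize mode {normalize!r}")


def state_ranking_report(
    models: DeepLDAModel | list[DeepLDAModel],
    state_samples: dict[str, np.ndarray],
    normalize: str = "sum",
) -> pd.DataFrame:
    """Tidy table (state, descriptor, weight) of per-state relevances.

    With several models (replica CVs), the reported weight is the mean over
    models, echoing the practice of averaging over independently trained CVs.
    """
    if isinstance(models, DeepLDAModel):
        models = [models]
    if len(state_samples) < 1:
        raise ValueError("need at least one labelled state")
    names = models[0].descriptor_names or [
        f"d_{i + 1}" for i in range(models[0].n_descriptors)
    ]
    rows = []
    for state, samples in state_samples.items():
        per_model = np.array(
            [descriptor_relevance(m, samples, normalize=normalize) for m in models]
        )
        mean_w = per_model.mean(axis=0)
        for name, wt in zip(names, mean_w):
            rows.append({"state": state, "descriptor": name, "weight": wt})
    return pd.DataFrame(rows)
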
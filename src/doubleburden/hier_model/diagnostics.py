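"""Convergence diagnostics: rank-normalised split R-hat and effective sample
size for monitored scalar summaries (computed via ArviZ)."""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["convergence_diagnostics", "RHAT_THRESHOLD", "ESS_THRESHOLD"]

RHAT_THRESHOLD = 1.05
ESS_THRESHOLD = 100.0


def convergence_diagnostics(summaries: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Diagnose chains of scalar summaries.

    ``summaries`` maps a name to a (n_chains, n_draws) array.  Returns a
    DataFrame indexed by name with columns ``rhat``, ``ess`` and ``flagged``
    (R-hat > 1.05 or ESS < 100, or an undefined diagnostic — e.g. constant
    chains — which is flagged rather than raised).

    Raises for fewer than 2 chains or fewer than 4 draws per chain.
    """
    import arviz as az

    rows = {}
    for name, chains in summaries.items():
        arr = np.asarray(chains, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"{name}: expected (n_chains, n_draws), got {arr.shape}")
        if arr.shape[0] < 2:
            raise ValueError(f"{name}: need >= 2 chains for split R-hat")
        if arr.shape[1] < 4:
            raise ValueError(f"{name}: need >= 4 draws per chain")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if np.allclose(arr, arr.flat[0]):
                rhat, ess = float("nan"), float("nan")
            else:
                dataset = az.convert_to_dataset(arr)
                rhat = float(az.rhat(dataset)["x"].values)
                ess = float(az.ess(dataset)["x"].values)
        flagged = (not np.isfinite(rhat) or not np.isfinite(ess)
                   or rhat > RHAT_THRESHOLD or ess < ESS_THRESHOLD)
        rows[name] = {"rhat": rhat, "ess": ess, "flagged": flagged}
    return pd.DataFrame.from_dict(rows, orient="index")
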
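"""Bundled empirical amino-acid replacement models (JTT, LG).

Each data file holds one line of 190 lower-triangle exchangeabilities and
one line of 20 stationary frequencies, both in PAML residue order
(ARNDCQEGHILKMFPSTWYV), matching :data:`parinv.AMINO_ACIDS`.
"""

from __future__ import annotations

from functools import lru_cache
from importlib.resources import files

import numpy as np

__all__ = ["load_empirical_model", "lg_frequencies"]


@lru_cache(maxsize=None)
def load_empirical_model(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (symmetric 20x20 exchangeabilities, stationary frequencies)."""
    key = name.lower()
    if key not in ("jtt", "lg"):
        raise ValueError(f"unknown substitution model {name!r}; available: JTT, LG")
    text = files("parinv.data").joinpath(f"{key}.txt").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    rates = np.array([float(x) for x in lines[0].split()])
    freqs = np.array([float(x) for x in lines[1].split()])
    if rates.shape != (190,) or freqs.shape != (20,):
        raise ValueError(f"malformed model data file for {name!r}")
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = rates[k]
            k += 1
    freqs = freqs / freqs.sum()
    return S, freqs


def lg_frequencies() -> np.ndarray:
    """LG stationary amino-acid frequencies (pseudo-count background)."""
    return load_empirical_model("lg")[1].copy()
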
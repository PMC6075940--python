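"""Family environments: SES as the richness of the home learning set.

Each simulated child receives a *family quotient*, uniform on
[0.60, 1.00], giving the probability that each verb of the full corpus is
present in the family's vocabulary.  The resulting inclusion mask is
fixed for the child's whole development (a type-frequency manipulation:
verbs are either available or not).  Assessment is always against the
full 500-verb set, like a standardised test administered to all
children.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

QUOTIENT_RANGE = (0.60, 1.00)
SES_CUT = 0.80


@dataclass
class FamilyEnvironment:
    quotient: float
    inclusion_mask: np.ndarray      # bool, one flag per corpus verb
    ses_group: str = ""             # "high" | "low", population-relative fields
    ses_quartile: int = 0           # 1..4, filled in by ses_split

    @property
    def n_included(self) -> int:
        return int(self.inclusion_mask.sum())


def sample_quotient(rng: np.random.Generator) -> float:
    return float(rng.uniform(*QUOTIENT_RANGE))


def build_family_set(n_verbs: int, quotient: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-verb inclusion with probability = quotient, then frozen."""
    if not 0.0 <= quotient <= 1.0:
        raise ValueError(f"quotient {quotient} outside [0, 1]")
    return rng.random(n_verbs) < quotient


def ses_split(quotients) -> pd.DataFrame:
    """High/low SES labels at the 0.80 cut and empirical quartile labels.

    A quotient of exactly 0.80 is assigned to the high group (a
    measure-zero tie under continuous sampling, fixed for
    reproducibility).  Quartiles are rank-based on the realised
    population, so the four quartile counts differ by at most one.
    """
    q = np.asarray(quotients, dtype=np.float64)
    if q.size == 0:
        raise ValueError("empty population")
    group = np.where(q >= SES_CUT, "high", "low")
    order = np.argsort(q, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(q.size)
    quartile = (rank * 4) // q.size + 1   # 1 = poorest environments
    return pd.DataFrame({"quotient": q, "ses_group": group, "ses_quartile": quartile})
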
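"""Shannon information content of structural properties across unfolding states.

For each property, the per-state mean unfolding fractions are renormalized to
a distribution f_oU over states; its Shannon entropy is compared with the
equal-fraction baseline f_eU, giving

    I = H(f_eU) − H(f_oU) = log₂(n_states) − H(f_oU)   (bits)

A property whose unfolding fraction is concentrated in few states carries high
information: it discriminates unfolding states. Runs (e.g. protein variants)
can be compared by each run's percentage share of a property's total I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .states import StateSummary


def _entropy(p: np.ndarray, base: float) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p) / np.log(base)).sum())


@dataclass
class InformationContent:
    property_names: list[str]
    information: np.ndarray  # per-property I
    observed_fractions: np.ndarray  # (n_states, n_properties), columns sum to 1
    n_states: int
    base: float = 2.0
    flat_properties: list[str] | None = None  # all-zero fractions → I = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"property": self.property_names, "I": self.information}
        )

    def rank(self) -> list[str]:
        order = np.argsort(-self.information, kind="stable")
        return [self.property_names[i] for i in order]


def information_content(
    summary: StateSummary, base: float = 2.0
) -> InformationContent:
    """Per-property information content from a per-state summary.

    ``summary.state_means`` supplies each property's per-state mean unfolding
    fraction; per property these are renormalized to sum 1 over states
    (f_oU) and compared with the uniform baseline. All-zero columns get
    I = 0 and are flagged; negative fractions are a domain error.
    """
    means = np.asarray(summary.state_means, dtype=float)
    if means.ndim != 2:
        raise ConfigError("state_means must be (n_states, n_properties)")
    if np.any(means < 0):
        raise ConfigError("unfolding fractions must be non-negative")
    k, p = means.shape
    h_equal = np.log(k) / np.log(base)
    info = np.zeros(p)
    fractions = np.zeros((k, p))
    flat: list[str] = []
    for j in range(p):
        total = means[:, j].sum()
        if total <= 0:
            flat.append(summary.property_names[j])
            fractions[:, j] = 1.0 / k
            continue
        f = means[:, j] / total
        fractions[:, j] = f
        info[j] = h_equal - _entropy(f, base)
    if flat:
        warnings.warn(f"properties with all-zero fractions set to I=0: {flat}")
    # clip away negative rounding noise
    info = np.maximum(info, 0.0)
    return InformationContent(
        property_names=list(summary.property_names),
        information=info,
        observed_fractions=fractions,
        n_states=k,
        base=base,
        flat_properties=flat,
    )


def species_contribution(
    ic_per_run: list[InformationContent], run_names: list[str]
) -> pd.DataFrame:
    """Each run's percentage share of every property's information content.

    Rows are properties, columns are runs; each row sums to 100. Properties
    with zero total I across runs get equal shares (flagged by warning).
    """
    if len(ic_per_run) != len(run_names):
        raise ConfigError("one run name per InformationContent required")
    if len(ic_per_run) < 1:
        raise ConfigError("at least one run required")
    names = ic_per_run[0].property_names
    for ic in ic_per_run[1:]:
        if ic.property_names != names:
            raise ConfigError("runs have mismatched property lists")
    I = np.stack([ic.information for ic in ic_per_run], axis=1)  # (p, runs)
    totals = I.sum(axis=1)
    shares = np.empty_like(I)
    zero = totals <= 0
    if np.any(zero):
        warnings.warn(
            f"zero total information for {list(np.asarray(names)[zero])}; "
            "equal shares assigned"
        )
        shares[zero] = 100.0 / I.shape[1]
    nz = ~zero
    shares[nz] = 100.0 * I[nz] / totals[nz, None]
    df = pd.DataFrame(shares, columns=run_names)
    df.insert(0, "property", names)
    return df
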
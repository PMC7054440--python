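"""Blueprint-constrained heuristic assembly of items into ordered modules.

The program blueprint fixes, for each of the 4 modules, how many items of
each skill pattern it contains (hard constraints) and qualitative targets
for difficulty, discrimination and shape complexity (soft constraints:
'easy', 'moderate-high', 'balanced', ...).  Assembly proceeds by greedy
seeding followed by pairwise-swap local search that exchanges same-pattern
items (between modules, or with unused bank items), minimizing a
band-deviation cost; hard constraints are satisfied exactly throughout.

Qualitative bands are quantified as quantile intervals of the bank
distribution for the *module mean* of each feature; testing modules 1 and
4 additionally carry a parallelism penalty on their mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import N_MODULES, SKILLS, blueprint_pattern_counts

__all__ = ["ModuleBlueprint", "AssemblyError", "assemble_modules", "order_items"]


class AssemblyError(ValueError):
    """Raised when the bank cannot satisfy the blueprint's hard constraints."""


#: qualitative band -> quantile interval for the module mean of a feature
BAND_INTERVALS = {
    "balanced": (0.35, 0.65),
    "easy": (0.0, 0.40),
    "low-moderate": (0.15, 0.50),
    "simple-moderate": (0.15, 0.50),
    "moderate-high": (0.55, 0.90),
    "complex-moderate": (0.50, 0.85),
}

#: targeted module properties: feature -> per-module band labels
DEFAULT_BANDS = {
    "difficulty": ("balanced", "easy", "moderate-high", "balanced"),
    "discrimination": ("balanced", "low-moderate", "moderate-high", "balanced"),
    "shape_complexity": ("balanced", "simple-moderate", "complex-moderate", "balanced"),
}


@dataclass
class ModuleBlueprint:
    """Hard pattern counts and soft feature bands for the 4 modules."""

    pattern_counts: dict = field(default_factory=blueprint_pattern_counts)
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    parallel_modules: tuple = (1, 4)
    parallel_weight: float = 2.0

    def __post_init__(self):
        per_module = np.zeros(N_MODULES, dtype=int)
        for counts in self.pattern_counts.values():
            per_module += np.asarray(counts)
        if not (per_module == 10).all():
            raise ValueError(f"blueprint module sizes {per_module.tolist()} must all be 10")


def _item_patterns(bank: pd.DataFrame) -> list:
    qcols = [c for c in SKILLS if c in bank.columns]
    if len(qcols) != len(SKILLS):
        raise ValueError("bank must contain the four skill columns")
    return [tuple(np.flatnonzero(row)) for row in bank[list(SKILLS)].to_numpy()]


def _assembly_cost(bank, assignment, blueprint, quantile_of):
    cost = 0.0
    feats = list(blueprint.bands)
    means = {f: np.zeros(N_MODULES) for f in feats}
    for m in range(N_MODULES):
        sel = assignment == m + 1
        for f in feats:
            mean_q = quantile_of[f](bank.loc[sel, f].mean())
            means[f][m] = mean_q
            lo, hi = BAND_INTERVALS[blueprint.bands[f][m]]
            cost += max(0.0, lo - mean_q) + max(0.0, mean_q - hi)
    m1, m2 = blueprint.parallel_modules
    for f in feats:
        cost += blueprint.parallel_weight * abs(means[f][m1 - 1] - means[f][m2 - 1])
    return cost


def assemble_modules(bank: pd.DataFrame, blueprint: ModuleBlueprint = None,
                     seed: int = 0, max_passes: int = 20) -> pd.DataFrame:
    """Assign bank items to the 4 modules under the blueprint.

    Returns the bank with an added ``module`` column (0 = unused).  Raises
    :class:`AssemblyError` listing deficient skill patterns when the bank
    is infeasible.
    """
    blueprint = blueprint or ModuleBlueprint()
    bank = bank.reset_index(drop=True).copy()
    patterns = _item_patterns(bank)
    rng = np.random.default_rng(seed)

    # feasibility check per pattern
    needed = {p: sum(c) for p, c in blueprint.pattern_counts.items()}
    have = {}
    for p in patterns:
        have[p] = have.get(p, 0) + 1
    deficient = {p: (needed[p], have.get(p, 0)) for p in needed
                 if have.get(p, 0) < needed[p]}
    if deficient:
        names = {p: " & ".join(SKILLS[i] for i in p) for p in deficient}
        msg = "; ".join(f"{names[p]}: need {n}, have {h}" for p, (n, h) in deficient.items())
        raise AssemblyError(f"bank cannot satisfy the blueprint: {msg}")

    feats = list(blueprint.bands)
    for f in feats:
        if f not in bank.columns:
            raise ValueError(f"bank lacks required feature column {f!r}")
    quantile_of = {}
    for f in feats:
        vals = np.sort(bank[f].to_numpy(dtype=float))

        def qfun(x, vals=vals):
            return float(np.searchsorted(vals, x, side="right")) / vals.size

        quantile_of[f] = qfun

    # greedy seeding: per pattern, spread items over modules in random order
    assignment = np.zeros(len(bank), dtype=int)
    for p, counts in blueprint.pattern_counts.items():
        pool = [i for i, pat in enumerate(patterns) if pat == p]
        pool = list(rng.permutation(pool))
        for m in range(N_MODULES):
            for _ in range(counts[m]):
                assignment[pool.pop()] = m + 1

    # pairwise-swap local search among same-pattern items
    cost = _assembly_cost(bank, assignment, blueprint, quantile_of)
    by_pattern = {}
    for i, p in enumerate(patterns):
        by_pattern.setdefault(p, []).append(i)
    for _ in range(max_passes):
        improved = False
        for p, items in by_pattern.items():
            for ai in range(len(items)):
                for bi in range(ai + 1, len(items)):
                    i, jj = items[ai], items[bi]
                    if assignment[i] == assignment[jj]:
                        continue
                    assignment[i], assignment[jj] = assignment[jj], assignment[i]
                    new_cost = _assembly_cost(bank, assignment, blueprint, quantile_of)
                    if new_cost < cost - 1e-12:
                        cost = new_cost
                        improved = True
                    else:
                        assignment[i], assignment[jj] = assignment[jj], assignment[i]
        if not improved:
            break

    out = bank.copy()
    out["module"] = assignment
    # verify hard constraints survived the search
    for p, counts in blueprint.pattern_counts.items():
        for m in range(N_MODULES):
            got = sum(1 for i, pat in enumerate(patterns)
                      if pat == p and assignment[i] == m + 1)
            assert got == counts[m], "hard blueprint constraint violated"
    return out


def order_items(module: pd.DataFrame, difficulty_col: str = "difficulty",
                id_col: str = "item_id") -> pd.DataFrame:
    """Order a module's items by ascending difficulty, ties by item ID."""
    return module.sort_values([difficulty_col, id_col], kind="stable").reset_index(drop=True)
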
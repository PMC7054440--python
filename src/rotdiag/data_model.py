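"""Domain types, validation and file I/O for the rotation-skill diagnostic pipeline.

The assessment design is a 4-module learning program (testing, learning,
learning, testing), each module holding 10 multiple-choice rotation items.
Four binary skills are measured, in canonical order

    (x90, y90, x180, y180)

i.e. 90-degree and 180-degree rotations about the x and y axes.  A person's
latent state at time t is an attribute profile alpha in {0,1}^4; an item j
declares the skills it requires through a Q-matrix row q_j with 1 or 2 ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical skill order used throughout the package
SKILLS = ("x90", "y90", "x180", "y180")
K = 4
N_MODULES = 4
ITEMS_PER_MODULE = 10

__all__ = [
    "SKILLS",
    "K",
    "N_MODULES",
    "ITEMS_PER_MODULE",
    "QMatrix",
    "QMatrixError",
    "ResponseDataset",
    "all_profiles",
    "dominates",
    "ideal_response_table",
    "profile_index",
    "validate_q_matrix",
    "blueprint_q_matrix",
    "blueprint_pattern_counts",
    "module_scores",
    "load_dataset",
    "save_dataset",
    "encode_covariates",
]


class QMatrixError(ValueError):
    """Raised when a Q-matrix violates the 1-or-2 skills-per-item design rule."""


def all_profiles(k: int = K) -> np.ndarray:
    """All 2^k binary attribute profiles as a (2^k, k) array.

    Profile index c encodes bit k of the profile as ``(c >> k) & 1``, so
    index 0 is the empty profile and 2^k - 1 the full master.
    """
    c = np.arange(2**k)
    return (c[:, None] >> np.arange(k)[None, :]) & 1


def profile_index(bits) -> int:
    """Integer index of a binary profile under the canonical bit encoding."""
    bits = np.asarray(bits, dtype=int)
    return int((bits << np.arange(bits.size)).sum())


def dominates(alpha, q) -> bool:
    """Attribute-profile dominance ``alpha >= q`` elementwise (alpha masters q)."""
    alpha = np.asarray(alpha)
    q = np.asarray(q)
    return bool(np.all(alpha >= q))


def ideal_response_table(q: np.ndarray, k: int = K) -> np.ndarray:
    """(2^k, J) 0/1 table: eta[c, j] = 1 iff profile c dominates Q-row j."""
    profiles = all_profiles(k)
    return (profiles[:, None, :] >= q[None, :, :]).all(axis=2).astype(np.int8)


@dataclass(frozen=True)
class QMatrix:
    """Validated J x K binary skill-specification matrix.

    entries: (J, K) int array in canonical skill order.
    module_of_item: (J,) int array with module labels in 1..4.
    """

    entries: np.ndarray
    module_of_item: np.ndarray

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    def items_in_module(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.module_of_item == module)

    def skill_counts_by_module(self) -> pd.DataFrame:
        """Per-module item counts for each observed skill pattern (blueprint layout)."""
        rows = []
        patterns = sorted({tuple(r) for r in self.entries.tolist()}, key=lambda p: (sum(p), p))
        for pat in patterns:
            label = ", ".join(s for s, b in zip(SKILLS, pat) if b)
            match = np.all(self.entries == np.array(pat), axis=1)
            counts = [int(np.sum(match & (self.module_of_item == m))) for m in range(1, N_MODULES + 1)]
            rows.append({"pattern": label, **{f"module_{m}": c for m, c in zip(range(1, 5), counts)}, "total": int(match.sum())})
        return pd.DataFrame(rows)


def validate_q_matrix(raw, module_of_item=None) -> QMatrix:
    """Validate a raw integer matrix as a Q-matrix.

    Every row must be binary with row sum 1 or 2 (items measure one or two
    skills).  Raises :class:`QMatrixError` naming the offending row, or
    ``TypeError`` for non-binary entries.
    """
    q = np.asarray(raw)
    if q.ndim != 2 or q.shape[1] != K:
        raise QMatrixError(f"Q-matrix must be two-dimensional with {K} columns, got shape {q.shape}")
    if not np.isin(q, (0, 1)).all():
        bad = np.argwhere(~np.isin(q, (0, 1)))[0]
        raise TypeError(f"non-binary Q-matrix entry at row {bad[0]}, column {bad[1]}")
    q = q.astype(np.int8)
    sums = q.sum(axis=1)
    bad_rows = np.flatnonzero((sums == 0) | (sums > 2))
    if bad_rows.size:
        r = int(bad_rows[0])
        raise QMatrixError(
            f"Q-matrix row {r} measures {int(sums[r])} skills; every item must measure 1 or 2"
        )
    if module_of_item is None:
        j = q.shape[0]
        if j % ITEMS_PER_MODULE:
            raise QMatrixError(f"{j} items cannot be split into modules of {ITEMS_PER_MODULE}")
        module_of_item = np.repeat(np.arange(1, j // ITEMS_PER_MODULE + 1), ITEMS_PER_MODULE)
    module_of_item = np.asarray(module_of_item, dtype=int)
    if module_of_item.shape[0] != q.shape[0]:
        raise QMatrixError("module_of_item length does not match the number of Q-matrix rows")
    return QMatrix(entries=q, module_of_item=module_of_item)


# Design-blueprint pattern counts per module, canonical skill order.
# Keys are skill index tuples; values are counts in modules 1..4.
_BLUEPRINT = {
    (0,): (1, 2, 1, 1),        # x90
    (2,): (1, 2, 1, 1),        # x180
    (1,): (1, 2, 1, 1),        # y90
    (3,): (1, 3, 2, 1),        # y180
    (0, 1): (2, 1, 2, 2),      # x90 & y90
    (0, 3): (2, 0, 1, 2),      # x90 & y180
    (2, 1): (2, 0, 2, 2),      # x180 & y90
}


def blueprint_pattern_counts() -> dict:
    """The design blueprint: skill-pattern -> per-module item counts (modules 1..4)."""
    return {tuple(sorted(k)): v for k, v in _BLUEPRINT.items()}


def blueprint_q_matrix() -> QMatrix:
    """The canonical 40-item Q-matrix implied by the module blueprint.

    Items are ordered by module; within a module, by the blueprint pattern
    order (single skills x90, x180, y90, y180, then the two-skill patterns).
    """
    rows = []
    modules = []
    for m in range(N_MODULES):
        for pat, counts in _BLUEPRINT.items():
            row = np.zeros(K, dtype=np.int8)
            row[list(pat)] = 1
            for _ in range(counts[m]):
                rows.append(row.copy())
                modules.append(m + 1)
    return validate_q_matrix(np.array(rows), np.array(modules))


@dataclass
class ResponseDataset:
    """Person x item binary responses and response times for the 4-module design.

    Y: (N, J) int 0/1 responses; L: (N, J) response times in seconds (> 0
    where observed); mask: (N, J) bool, True where the observation exists.
    Items are nested in modules (time points) via ``module_of_item``.
    """

    Y: np.ndarray
    L: np.ndarray
    module_of_item: np.ndarray
    person_ids: np.ndarray = None
    item_ids: np.ndarray = None
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=np.int8)
        self.L = np.asarray(self.L, dtype=float)
        self.module_of_item = np.asarray(self.module_of_item, dtype=int)
        n, j = self.Y.shape
        if self.L.shape != (n, j):
            raise ValueError(f"Y {self.Y.shape} and L {self.L.shape} shapes differ")
        if self.mask is None:
            self.mask = np.ones((n, j), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.person_ids is None:
            self.person_ids = np.arange(1, n + 1)
        if self.item_ids is None:
            self.item_ids = np.arange(1, j + 1)
        if not np.isin(self.Y[self.mask], (0, 1)).all():
            raise ValueError("responses must be binary")
        bad = self.mask & ~(self.L > 0)
        if bad.any():
            i, jj = np.argwhere(bad)[0]
            raise ValueError(
                f"non-positive response time for person {self.person_ids[i]}, "
                f"item {self.item_ids[jj]}: log-time is undefined"
            )
        mods = np.unique(self.module_of_item)
        if not np.array_equal(mods, np.arange(1, mods.size + 1)):
            raise ValueError("modules must be labeled 1..T contiguously")
        if j == N_MODULES * ITEMS_PER_MODULE:
            # the study design: 4 modules of exactly 10 items
            for m in range(1, N_MODULES + 1):
                cnt = int(np.sum(self.module_of_item == m))
                if cnt != ITEMS_PER_MODULE:
                    raise ValueError(
                        f"module {m} has {cnt} items, expected {ITEMS_PER_MODULE}")

    @property
    def n_persons(self) -> int:
        return self.Y.shape[0]

    @property
    def n_items(self) -> int:
        return self.Y.shape[1]


def module_scores(ds: ResponseDataset) -> pd.DataFrame:
    """Per-person number-correct score for each module (each in 0..10)."""
    cols = {}
    for m in range(1, int(ds.module_of_item.max()) + 1):
        idx = np.flatnonzero(ds.module_of_item == m)
        cols[f"module_{m}"] = (ds.Y[:, idx] * ds.mask[:, idx]).sum(axis=1)
    return pd.DataFrame(cols, index=pd.Index(ds.person_ids, name="person_id"))


STRATEGY_LEVELS = ("Analytic", "Holistic", "Combined")


def encode_covariates(table: pd.DataFrame) -> np.ndarray:
    """Dummy-code a covariate table into the (N, 5) design block.

    Columns produced, in order: gender (male=1), country (China=1),
    intervention (color=1), strategy1 (Analytic=1), strategy2 (Holistic=1);
    Combined strategy is the reference category.  Accepts either already
    0/1-coded columns or the string levels.
    """
    out = np.zeros((len(table), 5))
    mapping = {
        "gender": {"female": 0, "male": 1},
        "country": {"us": 0, "china": 1},
        "intervention": {"non-color": 0, "color": 1},
    }
    for i, col in enumerate(("gender", "country", "intervention")):
        v = table[col]
        if v.dtype == object:
            out[:, i] = v.str.lower().map(mapping[col]).to_numpy()
        else:
            out[:, i] = v.to_numpy()
    strat = table["strategy"]
    if strat.dtype == object:
        out[:, 3] = (strat == "Analytic").to_numpy()
        out[:, 4] = (strat == "Holistic").to_numpy()
    else:  # integer levels 0=Analytic, 1=Holistic, 2=Combined
        out[:, 3] = (strat == 0).to_numpy()
        out[:, 4] = (strat == 1).to_numpy()
    if np.isnan(out).any():
        raise ValueError("unrecognized covariate level")
    return out


def _long_to_wide(df: pd.DataFrame, value_name: str) -> pd.DataFrame:
    wide = df.pivot(index="person_id", columns="item_id", values="value")
    wide.columns.name = None
    return wide


def load_dataset(responses_path, rt_path, covariates_path, q_path):
    """Load the four CSV inputs and align them by person and item ID.

    responses.csv / rt.csv: long format with columns person_id, item_id,
    module, value.  q_matrix.csv: item_id, x90, y90, x180, y180, module.
    covariates.csv: person_id, gender, country, intervention, strategy.

    Returns ``(ResponseDataset, covariates DataFrame, QMatrix, report)``
    where report is a JSON-serializable validation summary.
    """
    resp = pd.read_csv(responses_path)
    rt = pd.read_csv(rt_path)
    cov = pd.read_csv(covariates_path)
    qdf = pd.read_csv(q_path)

    qdf = qdf.sort_values("item_id").reset_index(drop=True)
    q = validate_q_matrix(qdf[list(SKILLS)].to_numpy(), qdf["module"].to_numpy())
    item_ids = qdf["item_id"].to_numpy()

    wide_y = _long_to_wide(resp, "response")
    wide_l = _long_to_wide(rt, "rt")
    orphans = set(wide_y.index).symmetric_difference(wide_l.index) | (
        set(wide_y.index).symmetric_difference(cov["person_id"])
    )
    if orphans:
        raise ValueError(f"person IDs not present in all files: {sorted(orphans)[:10]}")
    missing_items = set(item_ids) - set(wide_y.columns)
    if missing_items:
        raise ValueError(f"items in Q-matrix but not in responses: {sorted(missing_items)[:10]}")

    cov = cov.set_index("person_id").loc[wide_y.index].reset_index()
    wide_l = wide_l.loc[wide_y.index, wide_y.columns]
    y = wide_y[item_ids].to_numpy()
    l = wide_l[item_ids].to_numpy()
    mask = ~np.isnan(y)
    ds = ResponseDataset(
        Y=np.nan_to_num(y, nan=0),
        L=np.where(mask, l, 1.0),
        module_of_item=q.module_of_item,
        person_ids=wide_y.index.to_numpy(),
        item_ids=item_ids,
        mask=mask,
    )
    report = {
        "n_persons": int(ds.n_persons),
        "n_items": int(ds.n_items),
        "missing_cells": int((~mask).sum()),
        "pattern_counts": q.skill_counts_by_module().to_dict(orient="records"),
    }
    return ds, cov, q, report


def save_dataset(ds: ResponseDataset, covariates: pd.DataFrame, q: QMatrix, out_dir):
    """Write responses.csv, rt.csv, covariates.csv and q_matrix.csv under out_dir."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recs_y, recs_l = [], []
    for i, pid in enumerate(ds.person_ids):
        for j, iid in enumerate(ds.item_ids):
            if not ds.mask[i, j]:
                continue
            m = int(ds.module_of_item[j])
            recs_y.append((pid, iid, m, int(ds.Y[i, j])))
            recs_l.append((pid, iid, m, float(ds.L[i, j])))
    cols = ["person_id", "item_id", "module", "value"]
    pd.DataFrame(recs_y, columns=cols).to_csv(out / "responses.csv", index=False)
    pd.DataFrame(recs_l, columns=cols).to_csv(out / "rt.csv", index=False)
    covariates.to_csv(out / "covariates.csv", index=False)
    qdf = pd.DataFrame(q.entries, columns=list(SKILLS))
    qdf.insert(0, "item_id", ds.item_ids)
    qdf["module"] = q.module_of_item
    qdf.to_csv(out / "q_matrix.csv", index=False)
    return out


def write_validation_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
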
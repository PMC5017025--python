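"""CSV readers and writers for study data and result tables.

Study CSV schema (UTF-8, header required), one row per concentration:

    study_id, arm, concentration, n_total, n_survived   (count form)
    study_id, arm, concentration, survival              (fraction form)

``arm`` is one of ``tox`` (toxicant alone), ``tox_env`` (toxicant under
environmental stress), ``env_only`` (environmental stressor alone,
concentration 0) and ``control`` (untreated, concentration 0). Counts are
converted to fractions on read; the environmental mortality of each pair
is Abbott-corrected from the env_only and control rows.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import DoseResponseDataset
from .errors import SchemaError
from .meta import StudyPair, compute_env_mortality

__all__ = ["read_study_csv", "write_study_csv", "write_results"]

_ARMS = {"tox", "tox_env", "env_only", "control"}


def _row_survival(row, idx):
    if "survival" in row.index and not pd.isna(row.get("survival")):
        s = float(row["survival"])
        n = float(row["n_total"]) if "n_total" in row.index and not pd.isna(row.get("n_total")) else None
    elif "n_survived" in row.index and not pd.isna(row.get("n_survived")):
        n = float(row["n_total"])
        if n <= 0:
            raise SchemaError(f"row {idx}: n_total must be > 0")
        s = float(row["n_survived"]) / n
    else:
        raise SchemaError(f"row {idx}: needs either a survival fraction or n_survived/n_total")
    if not 0.0 <= s <= 1.0:
        raise SchemaError(f"row {idx}: survival {s} outside [0, 1]")
    return s, n


def read_study_csv(path) -> list[StudyPair]:
    """Read and validate study pairs from the documented CSV schema.

    Raises :class:`SchemaError` naming the offending row for missing
    columns, out-of-range survival or duplicate (study, arm,
    concentration) triples.
    """
    df = pd.read_csv(path)
    required = {"study_id", "arm", "concentration"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing required columns: {sorted(missing)}")
    if not ({"survival"} <= set(df.columns) or {"n_survived", "n_total"} <= set(df.columns)):
        raise SchemaError("need either a 'survival' column or 'n_survived' and 'n_total'")
    bad_arm = df[~df["arm"].isin(_ARMS)]
    if len(bad_arm):
        raise SchemaError(
            f"row {bad_arm.index[0] + 2}: unknown arm {bad_arm['arm'].iloc[0]!r}"
        )
    dup = df.duplicated(subset=["study_id", "arm", "concentration"])
    if dup.any():
        raise SchemaError(f"row {df.index[dup.argmax()] + 2}: duplicate (study, arm, concentration)")

    pairs = []
    for study_id, group in df.groupby("study_id", sort=True):
        arms: dict[str, list] = {a: [] for a in _ARMS}
        for idx, row in group.iterrows():
            s, n = _row_survival(row, idx + 2)  # +2: header + 0-based index
            arms[row["arm"]].append((float(row["concentration"]), s, n))
        for ctrl_arm in ("control", "env_only"):
            if len(arms[ctrl_arm]) > 1:
                raise SchemaError(f"study {study_id}: multiple {ctrl_arm} rows")
        if not arms["control"]:
            raise SchemaError(f"study {study_id}: missing control arm")
        if not arms["env_only"]:
            raise SchemaError(f"study {study_id}: missing env_only arm")
        control_s = arms["control"][0][1]
        env_s = arms["env_only"][0][1]

        def _dataset(rows, control):
            rows = sorted(rows)
            conc = np.array([r[0] for r in rows])
            surv = np.array([r[1] for r in rows])
            ns = [r[2] for r in rows]
            weights = np.array(ns, dtype=float) if all(n is not None for n in ns) else None
            return DoseResponseDataset(conc, surv, control, weights)

        pairs.append(StudyPair(
            study_id=str(study_id),
            tox_arm=_dataset(arms["tox"], control_s),
            combined_arm=_dataset(arms["tox_env"], env_s),
            m_env=compute_env_mortality(env_s, control_s),
        ))
    return pairs


def write_study_csv(pairs, path, n_total: int | None = None):
    """Write study pairs in the standard schema (fraction form, plus
    counts when the arms carry weights or ``n_total`` is given)."""
    rows = []
    for pair in pairs:
        ctrl = pair.tox_arm.control_survival
        env = pair.combined_arm.control_survival
        rows.append({"study_id": pair.study_id, "arm": "control",
                     "concentration": 0.0, "survival": ctrl})
        rows.append({"study_id": pair.study_id, "arm": "env_only",
                     "concentration": 0.0, "survival": env})
        for arm_name, arm in (("tox", pair.tox_arm), ("tox_env", pair.combined_arm)):
            for i, (c, s) in enumerate(zip(arm.concentrations, arm.survival)):
                row = {"study_id": pair.study_id, "arm": arm_name,
                       "concentration": c, "survival": s}
                if arm.weights is not None:
                    row["n_total"] = int(arm.weights[i])
                    row["n_survived"] = int(round(s * arm.weights[i]))
                elif n_total is not None:
                    row["n_total"] = n_total
                    row["n_survived"] = int(round(s * n_total))
                rows.append(row)
    write_results(pd.DataFrame(rows), path)


def write_results(records, path, float_format: str = "%.6g"):
    """Write a result table as deterministic UTF-8 CSV.

    Accepts a DataFrame or a list of dataclass records; columns keep their
    first-seen order, floats are rendered at 6 significant digits.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        from dataclasses import asdict, is_dataclass
        rows = [asdict(r) if is_dataclass(r) else dict(r) for r in records]
        df = pd.DataFrame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format, encoding="utf-8")
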
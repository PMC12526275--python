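"""CSV schemas for dose-response, combination and gating datasets.

All three schemas are comma-separated UTF-8 text.  Lines starting with
``#`` before the header are comments; in the combination and gating
schemas they double as a ``# key: value`` metadata block.  Doses are
always μM and durations ms; a ``units`` annotation other than ``uM`` in
a dose-response file is rejected rather than silently converted.

Dose-response::

    # optional comments
    drug,dose_uM,fa[,rep_1,rep_2,...]
    peimine,1,0.0772

Combination::

    # components: peimine,peiminine
    # ratio: 1:1
    dose_1,dose_2,fa
    1,1,0.08071

Gating::

    # kind: boltzmann_activation
    # x_units: mV
    x,y
    -90,0.0001
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .combination import ComboDataset
from .dose_response import DoseResponseTable
from .gating import GATING_KINDS, GatingDataset

__all__ = [
    "read_dose_response_csv",
    "write_dose_response_csv",
    "read_combination_csv",
    "write_combination_csv",
    "read_gating_csv",
    "write_gating_csv",
]


class SchemaError(ValueError):
    """A CSV file violates its declared schema; message carries the line number."""


def _read_rows(path: str | Path) -> tuple[dict[str, str], list[str], list[tuple[int, list[str]]]]:
    """Split a file into (# metadata, header fields, numbered data rows)."""
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if header is None and ":" in line:
                    key, _, val = line.lstrip("#").partition(":")
                    meta[key.strip()] = val.strip()
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = [f.strip() for f in fields]
            else:
                rows.append((lineno, [f.strip() for f in fields]))
    if header is None:
        raise SchemaError(f"{path}: no header row found")
    return meta, header, rows


def _number(value: str, path: str | Path, lineno: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise SchemaError(
            f"{path}:{lineno}: non-numeric value {value!r} in column {column!r}"
        ) from None


def read_dose_response_csv(path: str | Path) -> DoseResponseTable:
    """Read one drug's dose-response table; rows may be in any order."""
    meta, header, rows = _read_rows(path)
    units = meta.get("units", "uM")
    if units != "uM":
        raise SchemaError(f"{path}: unsupported dose units {units!r}; only uM is accepted")
    required = ["drug", "dose_uM", "fa"]
    for col in required:
        if col not in header:
            raise SchemaError(f"{path}: missing required column {col!r} (header: {header})")
    rep_cols = [c for c in header if c.startswith("rep_")]
    idx = {c: header.index(c) for c in required + rep_cols}
    if not rows:
        raise SchemaError(f"{path}: no usable rows in data section")

    drugs, doses, fas, reps = set(), [], [], []
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise SchemaError(
                f"{path}:{lineno}: expected {len(header)} fields, found {len(fields)}"
            )
        drugs.add(fields[idx["drug"]])
        dose = _number(fields[idx["dose_uM"]], path, lineno, "dose_uM")
        if dose <= 0:
            raise SchemaError(f"{path}:{lineno}: dose must be positive, got {dose}")
        fa = _number(fields[idx["fa"]], path, lineno, "fa")
        if not 0.0 <= fa <= 1.0:
            raise SchemaError(f"{path}:{lineno}: fa must lie in [0, 1], got {fa}")
        if dose in doses:
            raise SchemaError(f"{path}:{lineno}: duplicate dose {dose} μM")
        doses.append(dose)
        fas.append(fa)
        if rep_cols:
            reps.append([_number(fields[idx[c]], path, lineno, c) for c in rep_cols])
    if len(drugs) != 1:
        raise SchemaError(
            f"{path}: a dose-response file must describe exactly one drug, found {sorted(drugs)}"
        )
    return DoseResponseTable.from_unsorted(
        drug_id=drugs.pop(),
        doses=np.array(doses),
        fa=np.array(fas),
        replicates=np.array(reps) if reps else None,
    )


def write_dose_response_csv(table: DoseResponseTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        fh.write("# units: uM\n")
        rep_cols = []
        if table.replicates is not None:
            rep_cols = [f"rep_{i + 1}" for i in range(table.replicates.shape[1])]
        writer.writerow(["drug", "dose_uM", "fa"] + rep_cols)
        for i, (dose, fa) in enumerate(zip(table.doses, table.fa)):
            row = [table.drug_id, repr(float(dose)), repr(float(fa))]
            if rep_cols:
                row += [repr(float(v)) for v in table.replicates[i]]
            writer.writerow(row)


def read_combination_csv(path: str | Path) -> ComboDataset:
    """Read a fixed-ratio combination dataset.

    The ``# components`` metadata line names the mixture components in
    column order; ``# ratio`` declares the design (e.g. ``1:1``), which
    every data row must realize.
    """
    meta, header, rows = _read_rows(path)
    if "components" not in meta:
        raise SchemaError(f"{path}: missing '# components:' metadata line")
    ids = tuple(s.strip() for s in meta["components"].split(",") if s.strip())
    k = len(ids)
    if k < 2:
        raise SchemaError(f"{path}: at least 2 components required, found {ids}")
    dose_cols = [f"dose_{i + 1}" for i in range(k)]
    for col in dose_cols + ["fa"]:
        if col not in header:
            raise SchemaError(f"{path}: missing required column {col!r} (header: {header})")
    ratio_label = meta.get("ratio", ":".join(["1"] * k))
    parts = [float(p) for p in ratio_label.split(":")]
    if len(parts) != k:
        raise SchemaError(f"{path}: ratio {ratio_label!r} does not match {k} components")
    weights = np.array(parts) / sum(parts)
    if not rows:
        raise SchemaError(f"{path}: no usable rows in data section")

    idx = {c: header.index(c) for c in dose_cols + ["fa"]}
    doses, fas = [], []
    for lineno, fields in rows:
        d = [_number(fields[idx[c]], path, lineno, c) for c in dose_cols]
        if any(v <= 0 for v in d):
            raise SchemaError(f"{path}:{lineno}: component doses must be positive, got {d}")
        ratios = np.array(d) / sum(d)
        if np.max(np.abs(ratios - weights)) > 1e-9:
            raise SchemaError(
                f"{path}:{lineno}: doses {d} violate the declared {ratio_label} ratio"
            )
        fa = _number(fields[idx["fa"]], path, lineno, "fa")
        if not 0.0 <= fa <= 1.0:
            raise SchemaError(f"{path}:{lineno}: fa must lie in [0, 1], got {fa}")
        doses.append(d)
        fas.append(fa)
    order = np.argsort(np.sum(doses, axis=1))
    return ComboDataset(
        component_ids=ids,
        weights=weights,
        doses=np.array(doses)[order],
        fa=np.array(fas)[order],
        design_label=ratio_label,
    )


def write_combination_csv(combo: ComboDataset, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# components: {','.join(combo.component_ids)}\n")
        fh.write(f"# ratio: {combo.design_label}\n")
        fh.write("# units: uM\n")
        writer = csv.writer(fh)
        k = len(combo.component_ids)
        writer.writerow([f"dose_{i + 1}" for i in range(k)] + ["fa"])
        for row, fa in zip(combo.doses, combo.fa):
            writer.writerow([repr(float(v)) for v in row] + [repr(float(fa))])


def read_gating_csv(path: str | Path) -> GatingDataset:
    """Read a gating curve; the ``# kind`` metadata line is required."""
    meta, header, rows = _read_rows(path)
    kind = meta.get("kind")
    if kind not in GATING_KINDS:
        raise SchemaError(
            f"{path}: '# kind:' metadata must name one of {GATING_KINDS}, got {kind!r}"
        )
    for col in ("x", "y"):
        if col not in header:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if not rows:
        raise SchemaError(f"{path}: no usable rows in data section")
    ix, iy = header.index("x"), header.index("y")
    xs = [_number(f[ix], path, n, "x") for n, f in rows]
    ys = [_number(f[iy], path, n, "y") for n, f in rows]
    order = np.argsort(xs)
    return GatingDataset(kind=kind, x=np.array(xs)[order], y=np.array(ys)[order])


def write_gating_csv(data: GatingDataset, path: str | Path) -> None:
    units = "mV" if data.kind.startswith("boltzmann") else "ms"
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# kind: {data.kind}\n")
        fh.write(f"# x_units: {units}\n")
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        for x, y in zip(data.x, data.y):
            writer.writerow([repr(float(x)), repr(float(y))])
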
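"""Table and configuration I/O.

All tables are tab-separated UTF-8 text with a fixed header and "." as the
decimal point, so that reruns with identical inputs produce byte-identical
outputs.  The complex configuration is YAML with an explicit
``schema_version`` string.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .model import (
    ComplexDefinition,
    ConfigError,
    FormatError,
    MonomerInfo,
    PeptideMeasurement,
    ProteinAmount,
    SampleMeta,
    ValidationError,
    receptor_complex,
)

log = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = "1.0"

PEPTIDE_COLUMNS = [
    "sample_id",
    "protein_id",
    "peptide_sequence",
    "charge",
    "endogenous_intensity",
    "reference_intensity",
    "spike_amount_amol",
]

SAMPLE_COLUMNS = [
    "sample_id",
    "sample_type",
    "timepoint",
    "replicate",
    "cell_equivalents",
    "injected_fraction",
    "treatment",
    "fraction_index",
]

PROFILE_COLUMNS = ["protein_id", "condition", "fraction_index", "intensity"]


def _read_tsv(path: str, required: Sequence[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def _num(value: str, column: str, row: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise FormatError(
            f"malformed numeric cell in column {column!r}, data row {row}: {value!r}"
        ) from None


def read_peptide_table(path: str) -> List[PeptideMeasurement]:
    """Read a peptide quantification table; row order is preserved.

    Raises :class:`FormatError` for missing columns or malformed numbers
    and :class:`ValidationError` (citing the 1-based data row) for values
    that violate domain invariants.
    """
    df = _read_tsv(path, PEPTIDE_COLUMNS)
    records: List[PeptideMeasurement] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                PeptideMeasurement(
                    sample_id=row.sample_id,
                    protein_id=row.protein_id,
                    peptide_sequence=row.peptide_sequence,
                    charge=int(_num(row.charge, "charge", i)),
                    endogenous_intensity=_num(
                        row.endogenous_intensity, "endogenous_intensity", i
                    ),
                    reference_intensity=_num(
                        row.reference_intensity, "reference_intensity", i
                    ),
                    spike_amount=_num(row.spike_amount_amol, "spike_amount_amol", i),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"data row {i}: {exc}") from None
    return records


def write_peptide_table(records: Iterable[PeptideMeasurement], path: str) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "protein_id": m.protein_id,
            "peptide_sequence": m.peptide_sequence,
            "charge": m.charge,
            "endogenous_intensity": repr(m.endogenous_intensity),
            "reference_intensity": repr(m.reference_intensity),
            "spike_amount_amol": repr(m.spike_amount),
        }
        for m in records
    ]
    pd.DataFrame(rows, columns=PEPTIDE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sample_table(path: str) -> Dict[str, SampleMeta]:
    df = _read_tsv(path, SAMPLE_COLUMNS)
    samples: Dict[str, SampleMeta] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        fraction = row.fraction_index
        try:
            meta = SampleMeta(
                sample_id=row.sample_id,
                sample_type=row.sample_type,
                timepoint=_num(row.timepoint, "timepoint", i),
                replicate=int(_num(row.replicate, "replicate", i)),
                cell_equivalents=_num(row.cell_equivalents, "cell_equivalents", i),
                injected_fraction=_num(row.injected_fraction, "injected_fraction", i),
                treatment=row.treatment or None,
                fraction_index=int(_num(fraction, "fraction_index", i))
                if fraction
                else None,
            )
        except ValidationError as exc:
            raise ValidationError(f"data row {i}: {exc}") from None
        if meta.sample_id in samples:
            raise ValidationError(f"duplicate sample_id {meta.sample_id!r} (row {i})")
        samples[meta.sample_id] = meta
    return samples


def write_sample_table(samples: Iterable[SampleMeta], path: str) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "sample_type": s.sample_type,
            "timepoint": repr(s.timepoint),
            "replicate": s.replicate,
            "cell_equivalents": repr(s.cell_equivalents),
            "injected_fraction": repr(s.injected_fraction),
            "treatment": s.treatment or "",
            "fraction_index": s.fraction_index if s.fraction_index is not None else "",
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_complex_config(path: str) -> List[ComplexDefinition]:
    """Read the YAML complex configuration.

    Schema::

        schema_version: "1.0"
        complexes:
          - name: receptor_core
            receptor: true          # exactly one complex in the file
            receptor_oligomer: 3
            reference_policy: most_abundant   # or "fixed:<protein_id>"
            members:
              - {protein: TNFR1, multiplicity: 3}

    A missing ``multiplicity`` defaults to 1 with a logged warning.
    """
    if not os.path.exists(path):
        raise ConfigError(f"no such file: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "complexes" not in doc:
        raise ConfigError(f"{path}: expected a mapping with a 'complexes' list")
    version = doc.get("schema_version")
    if version is None:
        raise ConfigError(f"{path}: missing schema_version")
    definitions: List[ComplexDefinition] = []
    names = set()
    for entry in doc["complexes"]:
        name = entry.get("name")
        if not name:
            raise ConfigError(f"{path}: complex entry without a name")
        if name in names:
            raise ConfigError(f"{path}: duplicate complex name {name!r}")
        names.add(name)
        members = []
        for m in entry.get("members", []):
            if "multiplicity" not in m:
                log.warning(
                    "complex %s member %s: multiplicity missing, defaulting to 1",
                    name,
                    m.get("protein"),
                )
            members.append((m["protein"], int(m.get("multiplicity", 1))))
        try:
            definitions.append(
                ComplexDefinition(
                    complex_name=name,
                    members=tuple(members),
                    reference_policy=entry.get("reference_policy", "most_abundant"),
                    receptor_flag=bool(entry.get("receptor", False)),
                    receptor_oligomer=int(entry.get("receptor_oligomer", 3)),
                )
            )
        except ValidationError as exc:
            raise ConfigError(f"{path}: complex {name}: {exc}") from None
    receptor_complex(definitions)  # raises ConfigError unless exactly one
    return definitions


def write_complex_config(complexes: Sequence[ComplexDefinition], path: str) -> None:
    doc = {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "complexes": [
            {
                "name": c.complex_name,
                "receptor": c.receptor_flag,
                "receptor_oligomer": c.receptor_oligomer,
                "reference_policy": c.reference_policy,
                "members": [
                    {"protein": pid, "multiplicity": mult} for pid, mult in c.members
                ],
            }
            for c in complexes
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_protein_amounts(path: str) -> List[ProteinAmount]:
    df = _read_tsv(
        path, ["sample_id", "protein_id", "amount_amol", "cv", "n_peptides"]
    )
    return [
        ProteinAmount(
            sample_id=row.sample_id,
            protein_id=row.protein_id,
            amount=_num(row.amount_amol, "amount_amol", i),
            cv=_num(row.cv, "cv", i),
            n_peptides=int(_num(row.n_peptides, "n_peptides", i)),
        )
        for i, row in enumerate(df.itertuples(index=False), start=1)
    ]


def write_protein_amounts(amounts: Iterable[ProteinAmount], path: str) -> None:
    rows = [
        {
            "sample_id": a.sample_id,
            "protein_id": a.protein_id,
            "amount_amol": repr(a.amount),
            "cv": repr(a.cv),
            "n_peptides": a.n_peptides,
        }
        for a in amounts
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "protein_id", "amount_amol", "cv", "n_peptides"]
    ).to_csv(path, sep="\t", index=False)


def read_monomer_table(path: str) -> Dict[str, MonomerInfo]:
    df = _read_tsv(path, ["protein_id", "monomer_mw_kda"])
    has_seq = "sequence" in df.columns
    out: Dict[str, MonomerInfo] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        info = MonomerInfo(
            protein_id=row.protein_id,
            monomer_mw=_num(row.monomer_mw_kda, "monomer_mw_kda", i),
            sequence=(row.sequence or None) if has_seq else None,
        )
        out[info.protein_id] = info
    return out


def write_monomer_table(monomers: Mapping[str, MonomerInfo], path: str) -> None:
    rows = [
        {
            "protein_id": m.protein_id,
            "monomer_mw_kda": repr(m.monomer_mw),
            "sequence": m.sequence or "",
        }
        for m in monomers.values()
    ]
    pd.DataFrame(rows, columns=["protein_id", "monomer_mw_kda", "sequence"]).to_csv(
        path, sep="\t", index=False
    )


def read_bnpage_table(path: str) -> pd.DataFrame:
    """Read a long-format gel-profile table into a typed DataFrame."""
    df = _read_tsv(path, PROFILE_COLUMNS)
    df = df.assign(
        fraction_index=df["fraction_index"].astype(int),
        intensity=df["intensity"].astype(float),
    )
    if (df["intensity"] < 0).any():
        raise ValidationError(f"{path}: negative intensity in profile table")
    return df


def write_bnpage_table(df: pd.DataFrame, path: str) -> None:
    out = df.loc[:, PROFILE_COLUMNS].copy()
    out["intensity"] = out["intensity"].map(repr)
    out.to_csv(path, sep="\t", index=False)


def config_hash(path: str) -> str:
    """SHA-256 of a configuration file, recorded in run summaries."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def write_run_summary(
    out_dir: str,
    stage: str,
    seed: Optional[int],
    parameters: Mapping,
    config_digest: Optional[str] = None,
) -> str:
    """Write a machine-readable run summary (JSON) for one pipeline stage."""
    os.makedirs(out_dir, exist_ok=True)
    payload = {
        "stage": stage,
        "seed": seed,
        "config_hash": config_digest,
        "parameters": dict(parameters),
    }
    path = os.path.join(out_dir, f"{stage}_summary.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
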
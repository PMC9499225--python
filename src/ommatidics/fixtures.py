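"""Packaged species-level data tables and their loaders.

Four tables ship with the package:

``table1``
    Species-level summaries for the four focal genera: cuticular brightness
    (mean +/- SE, n workers), foraging time and its three-way activity class,
    raw means and covariate-adjusted estimated marginal means (EMMs) for eye
    area, facet number, and facet diameter D, mesosoma length, and the
    per-genus covariate evaluation point for the EMMs.  26 species in all,
    23 with eye measurements and 3 measured only for the ocellus.
``table2``
    The 2 x 3 color (pale/dark) by activity (nocturnal/variable/diurnal)
    contingency counts.
``table5``
    The pale-species survey: 21 candidate taxa (brightness and relative eye
    size = eye area / mesosoma length) plus, per genus, one dark-reference
    row holding the largest relative eye size among five dark congeners.
``tableS1``
    The dark-reference rows alone (per-genus maxima; per-species values for
    the dark congeners are not published, only their maxima).

Fixture integrity is guarded by SHA-256 checksums of the packaged CSVs.
"""

from __future__ import annotations

import hashlib
import math
from importlib import resources
from typing import List

import numpy as np
import pandas as pd

from .model import ConfigurationError, ContingencyTable, SpeciesRecord, SurveyRecord

__all__ = [
    "FIXTURE_NAMES",
    "FIXTURE_SHA256",
    "load_fixture",
    "load_fixture_frame",
    "verify_fixtures",
]

FIXTURE_NAMES = ("table1", "table2", "table5", "tableS1")

# frozen at packaging time; verify_fixtures() recomputes and compares
FIXTURE_SHA256 = {
    "table1": "e4c448b4be5dd667d268b1b84c174483711bde10604aa4cd315e8f73f85c2796",
    "table2": "1343f0c953ecf1d009cc8e3ac59e41aea8e7a161e8835018860c337f7ee15787",
    "table5": "3e5fd42aadb3a48c30ec2926a9d4ef3937586fef7912d105f961bd328e4d1088",
    "tableS1": "00e3ff05cb91c5fc615384b01e4c9d0fd607b61c0693d7e6f843f5b817993c80",
}


def _fixture_bytes(name: str) -> bytes:
    if name not in FIXTURE_NAMES:
        raise ConfigurationError(
            f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}"
        )
    return resources.files("ommatidics.data").joinpath(f"{name}.csv").read_bytes()


def load_fixture_frame(name: str) -> pd.DataFrame:
    """Return the raw packaged table as a DataFrame."""
    import io

    return pd.read_csv(io.BytesIO(_fixture_bytes(name)))


def verify_fixtures() -> dict:
    """Recompute fixture checksums; return {name: bool} match flags."""
    out = {}
    for name in FIXTURE_NAMES:
        digest = hashlib.sha256(_fixture_bytes(name)).hexdigest()
        out[name] = digest == FIXTURE_SHA256[name]
    return out


def _color_class(b: float) -> str:
    # main-study rule; see colorimetry.classify_color
    if b > 65.0:
        return "pale"
    if b < 60.0:
        return "dark"
    return "indeterminate"


def _species_records(df: pd.DataFrame) -> List[SpeciesRecord]:
    records = []
    for row in df.itertuples(index=False):
        rec = SpeciesRecord(
            genus=row.genus,
            species=row.species,
            subfamily=row.subfamily,
            brightness_mean=float(row.brightness_mean),
            brightness_se=float(row.brightness_se),
            brightness_n=int(row.brightness_n),
            color_class=_color_class(float(row.brightness_mean)),
            activity_class=row.activity_class,
            foraging_raw=row.foraging_raw,
            eye_area_mean=_f(row.eye_area_mean),
            eye_area_se=_f(row.eye_area_se),
            eye_area_emm=_f(row.eye_area_emm),
            eye_area_emm_se=_f(row.eye_area_emm_se),
            facet_count_mean=_f(row.facet_count_mean),
            facet_count_se=_f(row.facet_count_se),
            facet_count_emm=_f(row.facet_count_emm),
            facet_count_emm_se=_f(row.facet_count_emm_se),
            facet_diameter_D_mean=_f(row.facet_diameter_D_mean),
            facet_diameter_D_se=_f(row.facet_diameter_D_se),
            facet_diameter_D_emm=_f(row.facet_diameter_D_emm),
            facet_diameter_D_emm_se=_f(row.facet_diameter_D_emm_se),
            mesosoma_mean=_f(row.mesosoma_mean),
            mesosoma_se=_f(row.mesosoma_se),
            emm_covariate_eval_point=_f(row.emm_covariate_eval_point),
        )
        records.append(rec)
    return records


def _f(x) -> float:
    return float(x) if pd.notna(x) else math.nan


def _survey_records(df: pd.DataFrame) -> List[SurveyRecord]:
    return [
        SurveyRecord(
            genus=row.genus,
            species=row.species,
            brightness_mean=_f(row.brightness_mean),
            relative_eye_size=float(row.relative_eye_size),
            role=row.role,
            brightness_n=int(row.brightness_n) if pd.notna(row.brightness_n) else 0,
        )
        for row in df.itertuples(index=False)
    ]


def load_fixture(name: str):
    """Load a packaged table as typed records.

    Returns a list of :class:`SpeciesRecord` for ``table1``, a
    :class:`ContingencyTable` for ``table2``, and lists of
    :class:`SurveyRecord` for ``table5`` / ``tableS1``.
    """
    df = load_fixture_frame(name)
    if name == "table1":
        return _species_records(df)
    if name == "table2":
        counts = df[["nocturnal", "variable", "diurnal"]].to_numpy()
        return ContingencyTable(
            row_labels=list(df["color"]),
            col_labels=["nocturnal", "variable", "diurnal"],
            counts=np.asarray(counts),
        )
    return _survey_records(df)
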
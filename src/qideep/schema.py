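"""Feature schema for the stroke screening table.

The study data is a provincial screening registry with 34 mixed
categorical/continuous clinical features (blood pressure, lifestyle,
laboratory panels, ...).  Each feature is described by a
:class:`FeatureSchema`: its short registry abbreviation, its kind, the
allowed integer codes for categorical features, a plausible value range for
continuous features, and — where clinically meaningful — the normal band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

__all__ = ["FeatureSchema", "default_schema", "schema_by_name",
           "schema_to_yaml", "schema_from_yaml"]

KINDS = ("binary", "ordinal", "continuous")


@dataclass(frozen=True)
class FeatureSchema:
    """Description of one clinical feature.

    Parameters
    ----------
    name : str
        Registry abbreviation (e.g. ``"LSBP"`` for left systolic blood
        pressure).
    kind : {"binary", "ordinal", "continuous"}
    codes : tuple of int, optional
        Allowed integer codes for categorical (binary/ordinal) features.
    range : (float, float), optional
        Plausible low/high values for continuous features.
    normal_range : (float, float), optional
        Clinical normal band; must lie inside ``range``.
    filler : bool
        True for features that pad the table to its full width of 34 and
        carry no documented registry coding.
    """

    name: str
    kind: str
    codes: Optional[tuple[int, ...]] = None
    range: Optional[tuple[float, float]] = None
    normal_range: Optional[tuple[float, float]] = None
    filler: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "continuous":
            if self.range is None or not self.range[0] < self.range[1]:
                raise ValueError(f"{self.name}: continuous feature needs low < high range")
            if self.normal_range is not None:
                lo, hi = self.normal_range
                if not (self.range[0] <= lo < hi <= self.range[1]):
                    raise ValueError(f"{self.name}: normal_range must lie inside range")
        else:
            if not self.codes:
                raise ValueError(f"{self.name}: categorical feature needs codes")


def _cont(name, lo, hi, normal=None, **kw):
    return FeatureSchema(name, "continuous", range=(float(lo), float(hi)),
                         normal_range=tuple(map(float, normal)) if normal else None, **kw)


def _bin(name, **kw):
    return FeatureSchema(name, "binary", codes=(0, 1), **kw)


def _ord(name, codes, **kw):
    return FeatureSchema(name, "ordinal", codes=tuple(codes), **kw)


def default_schema() -> list[FeatureSchema]:
    """The 34-feature schema of the screening table.

    The documented entries carry the registry codings (e.g. smoking coded
    2=yes / 1=quitting / 0=no; LSBP normal band 80–140 mmHg).  RSBP/RDBP
    (right-arm pressures) are coded analogously to the left-arm readings.
    The remaining features are labelled filler: they keep the table at its
    full width but have invented, plausible codings.
    """
    documented = [
        _bin("Arhm"),                                   # arrhythmia
        _cont("BMI", 14, 45, normal=(20, 25)),          # body mass index
        _ord("Edu", (1, 2, 3, 4, 5)),                   # education level
        _bin("Exs"),                                    # lack of exercise
        _cont("FA", 25, 95),                            # filling (survey) age, years
        _cont("FBG", 2.0, 20.0, normal=(3.9, 6.1)),     # fasting blood glucose, mmol/L
        _cont("HbA1c", 3.0, 15.0, normal=(4, 6)),       # glycosylated hemoglobin, %
        _cont("Hcy", 2.0, 60.0, normal=(5, 15)),        # homocysteine, umol/L
        _cont("HDL-C", 0.4, 3.0, normal=(1.16, 1.55)),  # HDL cholesterol, mmol/L
        _bin("HEH"),                                    # history of hypertension
        _bin("HS"),                                     # history of stroke
        _cont("Ht", 140, 200),                          # height, cm
        _cont("Wt", 35, 130),                           # weight, kg
        _cont("LDBP", 40, 130, normal=(60, 89)),        # left diastolic BP, mmHg
        _cont("LDL-C", 0.3, 8.0, normal=(0.3, 3.37)),   # LDL cholesterol, < 3.37 mmol/L
        _cont("LSBP", 70, 220, normal=(80, 140)),       # left systolic BP, mmHg
        _ord("MV", (1, 2, 3)),                          # meat/vegetable balance
        _bin("Ret"),                                    # retired
        _ord("Sm", (0, 1, 2)),                          # smoking: 2 yes, 1 quit, 0 no
        _cont("TC", 2.0, 12.0, normal=(3, 5.2)),        # total cholesterol, mmol/L
        _cont("TG", 0.2, 10.0, normal=(0.6, 1.7)),      # triglyceride, mmol/L
        _cont("Ys", 0, 60),                             # years of smoking; 0 for nonsmokers
        _cont("RSBP", 70, 220, normal=(80, 140)),       # right systolic BP, mmHg
        _cont("RDBP", 40, 130, normal=(60, 89)),        # right diastolic BP, mmHg
    ]
    fillers = [
        _bin("Sex", filler=True),
        _bin("FHS", filler=True),                       # family history of stroke
        _ord("Flv", (1, 2, 3), filler=True),            # diet flavour (light..salty)
        _bin("Dm", filler=True),                        # diabetes history
        _bin("HHD", filler=True),                       # heart disease history
        _bin("Obs", filler=True),                       # clinically obese
        _ord("Alc", (0, 1, 2), filler=True),            # alcohol: none/occasional/regular
        _bin("Mar", filler=True),                       # married / cohabiting
        _ord("Occ", (1, 2, 3, 4), filler=True),         # occupation class
        _bin("Ins", filler=True),                       # medical insurance
    ]
    schema = documented + fillers
    names = [f.name for f in schema]
    assert len(names) == 34 and len(set(names)) == 34
    return schema


def schema_by_name(schema: list[FeatureSchema]) -> dict[str, FeatureSchema]:
    return {f.name: f for f in schema}


def schema_to_yaml(schema: list[FeatureSchema], path) -> None:
    payload = []
    for f in schema:
        d = asdict(f)
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in d.items() if v is not None and v is not False}
        d.setdefault("filler", f.filler)
        payload.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def schema_from_yaml(path) -> list[FeatureSchema]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    out = []
    for d in payload:
        out.append(FeatureSchema(
            name=d["name"], kind=d["kind"],
            codes=tuple(d["codes"]) if d.get("codes") else None,
            range=tuple(d["range"]) if d.get("range") else None,
            normal_range=tuple(d["normal_range"]) if d.get("normal_range") else None,
            filler=bool(d.get("filler", False)),
        ))
    return out
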
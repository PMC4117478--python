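"""Cap-structure enumeration and ppm-tolerance assignment of observed masses.

Precursor-mass MS identifies a cap dinucleotide only up to its elemental
formula: positional isomers (e.g. N2,N2- versus N2,7-dimethylguanosine) and
the orientation of the 5'-5' pair are indistinguishable.  Candidates are
therefore reported in *isobar groups* — sets of structures sharing one
formula — and labels are compared orientation- and isomer-insensitively.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import (
    DEFAULT_BASE_METHYL_MAX,
    CapStructure,
    ElementalFormula,
    Nucleoside,
    anion_mass,
    ppm_error,
)

__all__ = [
    "FRACTIONS",
    "AlphabetConfig",
    "MassObservation",
    "Candidate",
    "IsobarGroup",
    "MatchResult",
    "enumerate_caps",
    "parse_cap_label",
    "canonical_label",
    "match_observation",
    "match_table",
    "classify_cap_type",
    "load_reference_detection_matrix",
    "fraction_specific_structures",
    "is_unknown_label",
    "cross_validate",
    "ms_cap_identities",
]

#: LC size-fraction vocabulary (nt) used for MS observations.
FRACTIONS = ("20-50", "50-100", ">100")

_FRACTION_COLUMNS = {
    "20-50": "detect_20_50",
    "50-100": "detect_50_100",
    ">100": "detect_gt100",
}

DEFAULT_TOLERANCE_PPM = 5.0


@dataclass(frozen=True)
class AlphabetConfig:
    """The enumerable methylation space for candidate caps.

    ``base_methyl_max`` caps the number of base N-methyls per base;
    ``allow_ribose_methyl`` lets every nucleoside optionally carry one
    2'-O-methyl.  The default covers every assigned structure in the
    reference detection matrix without exploding the search space.
    """

    base_methyl_max: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BASE_METHYL_MAX)
    )
    allow_ribose_methyl: bool = True

    @classmethod
    def from_dict(cls, d: Mapping) -> "AlphabetConfig":
        return cls(
            base_methyl_max=dict(d.get("base_methyl_max", DEFAULT_BASE_METHYL_MAX)),
            allow_ribose_methyl=bool(d.get("allow_ribose_methyl", True)),
        )

    def nucleosides(self) -> list[Nucleoside]:
        out = []
        for base, mmax in sorted(self.base_methyl_max.items()):
            for bm in range(mmax + 1):
                for rm in ((False, True) if self.allow_ribose_methyl else (False,)):
                    out.append(Nucleoside(base, bm, rm))
        return out


@dataclass(frozen=True)
class MassObservation:
    """One observed [M-H]- mass from a size-fractionated LC-MS run."""

    observed_mass: float
    fraction: str = "20-50"
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.observed_mass <= 0:
            raise ValueError("observed mass must be positive")
        if self.fraction not in FRACTIONS:
            raise ValueError(f"fraction {self.fraction!r} not in {FRACTIONS}")


@dataclass(frozen=True)
class Candidate:
    cap: CapStructure
    calculated_mass: float
    ppm: float

    @property
    def label(self) -> str:
        return self.cap.canonical_label


@dataclass(frozen=True)
class IsobarGroup:
    """Candidates sharing one elemental formula (indistinguishable by mass)."""

    formula: ElementalFormula
    members: tuple[Candidate, ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.members)

    @property
    def ppm(self) -> float:
        return self.members[0].ppm


@dataclass
class MatchResult:
    observation: MassObservation
    candidates: list[Candidate]
    isobar_groups: list[IsobarGroup]
    status: str  # "matched" | "unknown"
    nearest: list[Candidate] = field(default_factory=list)


def enumerate_caps(config: AlphabetConfig | None = None) -> list[CapStructure]:
    """All distinct unordered cap dinucleotides under the alphabet config.

    Each unordered pair appears once, stored in conventional display
    orientation; the list is sorted by anion mass, then label, so output is
    deterministic.
    """
    config = config or AlphabetConfig()
    nucs = config.nucleosides()
    if not nucs:
        raise ValueError("empty alphabet")
    seen: dict[str, CapStructure] = {}
    for a, b in combinations_with_replacement(nucs, 2):
        cap = CapStructure(*_display_pair(a, b))
        seen.setdefault(cap.canonical_label, cap)
    return sorted(seen.values(), key=lambda c: (c.anion_mass, c.canonical_label))


def _display_pair(a: Nucleoside, b: Nucleoside) -> tuple[Nucleoside, Nucleoside]:
    from .chem import _display_order

    return _display_order(a, b)


_SIDE_RE = re.compile(r"^(?:(\d)?m)?([ACGU])(m)?$")


def parse_cap_label(label: str) -> CapStructure | None:
    """Parse a label like ``3mGpppAm`` (or ``3mGpppAm/Amppp3mG``) to a structure.

    Retention-time isomer suffixes ``(1)``/``(2)`` are dropped — they carry
    no compositional information.  Returns ``None`` for labels containing an
    unknown moiety (``Yn``).
    """
    primary = label.split("/")[0].strip()
    primary = re.sub(r"\(\d+\)", "", primary)
    try:
        left, right = primary.split("ppp")
    except ValueError as exc:
        raise ValueError(f"not a cap dinucleotide label: {label!r}") from exc
    sides = []
    for part in (left, right):
        m = _SIDE_RE.match(part)
        if m is None:
            return None  # unknown moiety such as Y1
        count, base, ribose = m.groups()
        bm = 1 if (count is None and part.startswith("m")) else int(count or 0)
        sides.append(Nucleoside(base, bm, ribose is not None))
    return CapStructure(*_display_pair(*sides))


def canonical_label(label_or_cap) -> str:
    """Orientation/isomer-insensitive form of a label for comparisons."""
    if isinstance(label_or_cap, CapStructure):
        return label_or_cap.canonical_label
    cap = parse_cap_label(label_or_cap)
    if cap is None:
        return re.sub(r"\(\d+\)", "", str(label_or_cap).split("/")[0].strip())
    return cap.canonical_label


def match_observation(
    obs: MassObservation,
    candidates: Sequence[CapStructure] | None = None,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
    n_nearest: int = 3,
) -> MatchResult:
    """Assign an observed [M-H]- mass to candidate caps within a ppm tolerance.

    Returns every candidate with |ppm| <= tolerance, sorted by |ppm| and
    partitioned into isobar groups (also sorted by |ppm|).  When nothing is
    in tolerance the status is ``unknown`` and the nearest out-of-tolerance
    candidates are attached so unmatched masses never silently disappear.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive ppm")
    caps = list(candidates) if candidates is not None else enumerate_caps()
    scored = [
        Candidate(cap, cap.anion_mass, ppm_error(obs.observed_mass, cap.anion_mass))
        for cap in caps
    ]
    scored.sort(key=lambda c: (abs(c.ppm), c.label))
    hits = [c for c in scored if abs(c.ppm) <= tolerance_ppm]
    groups: dict[ElementalFormula, list[Candidate]] = {}
    for c in hits:
        groups.setdefault(c.cap.neutral_formula, []).append(c)
    isobar_groups = sorted(
        (IsobarGroup(f, tuple(members)) for f, members in groups.items()),
        key=lambda g: abs(g.ppm),
    )
    if hits:
        return MatchResult(obs, hits, isobar_groups, "matched")
    return MatchResult(obs, [], [], "unknown", nearest=scored[:n_nearest])


def match_table(
    observations: Iterable[MassObservation],
    candidates: Sequence[CapStructure] | None = None,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
) -> pd.DataFrame:
    """Match many observations; one row per (observation, candidate).

    Unknown observations yield a single row with empty label and their
    nearest candidate noted for curation.
    """
    caps = list(candidates) if candidates is not None else enumerate_caps()
    rows = []
    for obs in observations:
        res = match_observation(obs, caps, tolerance_ppm)
        if res.status == "unknown":
            near = res.nearest[0] if res.nearest else None
            rows.append(
                {
                    "identifier": obs.identifier,
                    "fraction": obs.fraction,
                    "observed_mass": obs.observed_mass,
                    "label": "",
                    "calculated_mass": float("nan"),
                    "error_ppm": float("nan"),
                    "isobar_group": -1,
                    "cap_type": "",
                    "status": "unknown",
                    "nearest_label": near.label if near else "",
                    "nearest_ppm": round(near.ppm, 2) if near else float("nan"),
                }
            )
            continue
        group_of = {
            c.label: gi for gi, g in enumerate(res.isobar_groups) for c in g.members
        }
        for c in res.candidates:
            rows.append(
                {
                    "identifier": obs.identifier,
                    "fraction": obs.fraction,
                    "observed_mass": obs.observed_mass,
                    "label": c.label,
                    "calculated_mass": round(c.calculated_mass, 6),
                    "error_ppm": round(c.ppm, 2),
                    "isobar_group": group_of[c.label],
                    "cap_type": classify_cap_type(c.cap),
                    "status": "matched",
                    "nearest_label": "",
                    "nearest_ppm": float("nan"),
                }
            )
    return pd.DataFrame(rows)


def classify_cap_type(cap: CapStructure) -> str:
    """``type0`` when the first transcribed nucleotide has no 2'-O-methyl."""
    return cap.cap_type


def load_reference_detection_matrix() -> pd.DataFrame:
    """The packaged per-fraction detection summary of cap structures.

    Columns: label, detect_20_50 / detect_50_100 / detect_gt100
    ("detected"/"ND"), calculated_mass, observed_mass, error_ppm.  Unknown
    (Yn) structures have no calculated mass.
    """
    ref = importlib.resources.files("capscape.data") / "cap_detection_reference.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def is_unknown_label(label: str) -> bool:
    """True for labels containing an uncharacterised (Yn) moiety."""
    return bool(re.search(r"Y\d+", label))


def fraction_specific_structures(
    matrix: pd.DataFrame, fraction: str, include_unknowns: bool = False
) -> list[str]:
    """Labels detected in ``fraction`` and in no other size fraction."""
    if fraction not in _FRACTION_COLUMNS:
        raise ValueError(f"fraction {fraction!r} not in {tuple(_FRACTION_COLUMNS)}")
    if matrix.empty:
        return []
    target = _FRACTION_COLUMNS[fraction]
    others = [c for c in _FRACTION_COLUMNS.values() if c != target]
    mask = (matrix[target] == "detected") & (matrix[others] == "ND").all(axis=1)
    labels = matrix.loc[mask, "label"]
    if not include_unknowns:
        labels = labels[~labels.map(is_unknown_label)]
    return [lab.split("/")[0] for lab in labels]


#: Conventional spot names per G-side base-methyl count.  Mass alone cannot
#: place the methyls, so count 2 is reported under one conventional name.
G_METHYL_SPOT_NAME = {0: "Gp", 1: "7mGp", 2: "2,2mGp", 3: "2,2,7mGp"}

#: nt span covered by each fraction label, for coverage reporting.  Keys mix
#: the MS (20-50/50-100/>100) and TLC/gel (<50/50-100/100-200) vocabularies.
_FRACTION_SPAN = {
    "20-50": (20, 50),
    "<50": (20, 50),
    "50-100": (50, 100),
    ">100": (100, 200),
    "100-200": (100, 200),
}


def ms_cap_identities(matrix: pd.DataFrame) -> dict[str, set[str]]:
    """Collapse assigned MS cap rows to 5'-cap identities with their fractions.

    Each assigned dinucleotide is keyed by the conventional monophosphate
    spot name of its most-methylated guanosine side (e.g. ``3mGpppAm`` in
    all fractions -> ``2,2,7mGp: {20-50, 50-100, >100}``), the identity
    under which TLC sees the same cap after pyrophosphatase cleavage.
    """
    out: dict[str, set[str]] = {}
    for _, row in matrix.iterrows():
        if is_unknown_label(row["label"]):
            continue
        cap = parse_cap_label(row["label"])
        g_methyls = max(
            (n.base_methyls for n in (cap.outer, cap.inner) if n.base == "G"),
            default=None,
        )
        if g_methyls is None:
            continue
        key = G_METHYL_SPOT_NAME[g_methyls]
        fracs = {
            frac for frac, col in _FRACTION_COLUMNS.items() if row[col] == "detected"
        }
        out.setdefault(key, set()).update(fracs)
    return out


def cross_validate(
    tlc_identifications: Mapping[str, Iterable[str]],
    ms_identifications: Mapping[str, Iterable[str]],
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Join cap identities seen by both TLC and MS.

    Both inputs map a 5'-cap identity (spot label) to the size fractions in
    which it was seen.  Returns the cross-validated table (identity, the
    fractions per technique, and the nt span covered by their union) plus
    residual lists of identities seen by only one technique.
    """
    tlc = {k: set(v) for k, v in tlc_identifications.items()}
    ms = {k: set(v) for k, v in ms_identifications.items()}
    shared = sorted(tlc.keys() & ms.keys())
    rows = []
    for key in shared:
        spans = [_FRACTION_SPAN[f] for f in (tlc[key] | ms[key]) if f in _FRACTION_SPAN]
        if spans:
            lo = min(s[0] for s in spans)
            hi = max(s[1] for s in spans)
            coverage = f"{lo} nt-{hi} nt"
        else:
            coverage = ""
        rows.append(
            {
                "identity": key,
                "tlc_fractions": ",".join(sorted(tlc[key])),
                "ms_fractions": ",".join(sorted(ms[key])),
                "coverage": coverage,
            }
        )
    validated = pd.DataFrame(rows, columns=["identity", "tlc_fractions", "ms_fractions", "coverage"])
    tlc_only = sorted(tlc.keys() - ms.keys())
    ms_only = sorted(ms.keys() - tlc.keys())
    return validated, tlc_only, ms_only
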
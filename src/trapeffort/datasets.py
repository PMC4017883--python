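"""Published summary data from the Gutianshan camera-trap survey.

The two-year (June 2009 – May 2011) survey of a 24-ha plot in
Gutianshan National Nature Reserve ran 19 cameras simultaneously and
recorded 20 species.  The per-species photograph counts below are the
published summary table of that survey: RP is the number of recorded
photographs, IP the number of independent photographs after the 30-min
filter.  Guild assignments follow the study's exclusion lists (seven
arboreal birds and squirrels; three transients judged non-resident).

The per-day detection matrix underlying the survey's rarefaction curve
is not redistributed here; :func:`synthetic_daily_matrix` builds a
synthetic stand-in calibrated to the published counts instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import IncidenceMatrix, species_summary_from_counts

__all__ = [
    "GUTIANSHAN_N_CAMERAS",
    "GUTIANSHAN_N_DAYS",
    "GUTIANSHAN_CAMERA_DAYS",
    "gutianshan_species_table",
    "gutianshan_classification",
    "gutianshan_summary",
    "synthetic_daily_matrix",
]

GUTIANSHAN_N_CAMERAS = 19
GUTIANSHAN_N_DAYS = 730
#: total trapping effort reported by the survey (slightly below
#: 19 x 730 = 13,870, implying minor unrecorded camera downtime)
GUTIANSHAN_CAMERA_DAYS = 13_824

# species, latin name, guild, recorded photographs, independent photographs
_SPECIES_ROWS = [
    ("Chinese bamboo partridge", "Bambusicola thoracicus", "transient", 3, 3),
    ("Silver pheasant", "Lophura nycthemera", "resident_terrestrial", 290, 158),
    ("Elliot's pheasant", "Syrmaticus ellioti", "resident_terrestrial", 48, 37),
    ("Koklass pheasant", "Pucrasia macrolopha", "transient", 1, 1),
    ("Grey-headed woodpecker", "Picus canus", "arboreal", 8, 5),
    ("Fairy pitta", "Pitta nympha", "arboreal", 1, 1),
    ("Golden mountain thrush", "Zoothera dauma", "arboreal", 16, 15),
    ("White-browed thrush", "Turdus obscurus", "arboreal", 1, 1),
    ("Pale thrush", "Turdus pallidus", "arboreal", 4, 4),
    ("Great necklaced laughingthrush", "Garrulax pectoralis", "arboreal", 3, 3),
    ("Confucian niviventer", "Niviventer confucianus", "resident_terrestrial", 1099, 826),
    ("Edwards's long-tailed giant rat", "Leopoldamys edwardsi", "resident_terrestrial", 59, 30),
    ("Pallas's squirrel", "Callosciurus erythraeus", "arboreal", 30, 19),
    ("Masked palm civet", "Paguma larvata", "resident_terrestrial", 95, 89),
    ("Hog badger", "Arctonyx collaris", "resident_terrestrial", 81, 36),
    ("Small-toothed ferret-badger", "Melogale moschata", "resident_terrestrial", 8, 7),
    ("Eurasian badger", "Meles meles", "transient", 11, 7),
    ("Wild boar", "Sus scrofa", "resident_terrestrial", 196, 34),
    ("Reeves muntjac", "Muntiacus reevesi", "resident_terrestrial", 643, 242),
    ("Black muntjac", "Muntiacus crinifrons", "resident_terrestrial", 709, 268),
]


def gutianshan_species_table() -> pd.DataFrame:
    """Published per-species counts with guild classification."""
    return pd.DataFrame(
        _SPECIES_ROWS, columns=["species", "latin", "guild", "rp", "ip"]
    ).set_index("species")


def gutianshan_classification() -> dict[str, str]:
    """Species -> guild mapping for the published community."""
    return gutianshan_species_table()["guild"].to_dict()


def gutianshan_summary() -> pd.DataFrame:
    """Species summary (RP, IP, P1, P2) recomputed from the published counts."""
    table = gutianshan_species_table()
    return species_summary_from_counts(
        rp=table["rp"],
        ip=table["ip"],
        resident=table.index[table["guild"] == "resident_terrestrial"],
    )


def synthetic_daily_matrix(seed: int | None = 0) -> IncidenceMatrix:
    """Synthetic stand-in for the survey's daily detection matrix.

    The real 730-day x 10-resident-species matrix is not redistributed
    with this package.  This builds a synthetic replacement calibrated
    only to the published independent-photograph counts: under a
    homogeneous Poisson detection process, species i with IP_i events
    over 730 monitoring days is detected on a given day with probability
    1 - exp(-IP_i / 730), giving an expected number of detection days

        D_i = round(730 * (1 - exp(-IP_i / 730))).

    The D_i detection days of each species are placed uniformly at
    random (seeded).  Exact rarefaction and the Chao estimator depend on
    the matrix only through the D_i, so these analyses are insensitive
    to the placement; cell values are 0/1 (which cameras detected the
    species on a day is not reconstructable from the published counts).
    """
    table = gutianshan_species_table()
    resident = table[table["guild"] == "resident_terrestrial"]
    n_days = GUTIANSHAN_N_DAYS
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(1, n_days + 1, name="day"), columns=resident.index
    )
    for species, ip in resident["ip"].items():
        d_i = int(round(n_days * (1.0 - np.exp(-ip / n_days))))
        days = rng.choice(n_days, size=d_i, replace=False)
        counts.iloc[days, counts.columns.get_loc(species)] = 1
    return IncidenceMatrix(counts=counts, unit_kind="day", max_count=GUTIANSHAN_N_CAMERAS)
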
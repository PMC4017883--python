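import numpy as np
import pandas as pd
import pytest

from trapeffort import (
    SurveyDesign,
    apply_exclusions,
    build_incidence,
    default_community,
    filter_independent,
    simulate_survey,
    site_day_occupancy,
    summarize_species,
)
from trapeffort.events import IncidenceMatrix

SPAN = (pd.Timestamp("2009-06-01"), pd.Timestamp("2009-06-01") + pd.Timedelta(days=729))


def incidence_from_counts(occurrences, n_units, unit_kind="day"):
    """Incidence matrix with given per-species unit-occurrence counts.

    Species i occupies the first ``occurrences[i]`` units; exact
    rarefaction and Chao depend only on these counts.
    """
    counts = np.zeros((n_units, len(occurrences)), dtype=int)
    for i, d_i in enumerate(occurrences):
        counts[:d_i, i] = 1
    frame = pd.DataFrame(counts, columns=[f"sp{i}" for i in range(len(occurrences))])
    return IncidenceMatrix(counts=frame, unit_kind=unit_kind)


@pytest.fixture
def toy_incidence():
    """4 units; species occurrence counts 4, 2, 1."""
    return incidence_from_counts([4, 2, 1], n_units=4)


@pytest.fixture(scope="session")
def full_sim():
    """Full-scale synthetic survey: 19 sites, 730 days, 20 species."""
    design = SurveyDesign(seed=42)
    community = default_community(42, design)
    records, truth = simulate_survey(design, community)
    return design, community, records, truth


@pytest.fixture(scope="session")
def full_processed(full_sim):
    design, community, records, truth = full_sim
    events = filter_independent(records)
    classification = {sp.name: sp.guild for sp in community}
    resident, _ = apply_exclusions(events, classification)
    summary = summarize_species(events, resident)
    incidence = build_incidence(resident, "day", SPAN)
    occupancy = site_day_occupancy(resident, SPAN, sites=design.site_ids)
    return {
        "design": design,
        "community": community,
        "records": records,
        "truth": truth,
        "events": events,
        "resident": resident,
        "summary": summary,
        "incidence": incidence,
        "occupancy": occupancy,
    }


def make_records(rows):
    """Photo-record frame from (site, species, iso timestamp) tuples."""
    frame = pd.DataFrame(rows, columns=["site_id", "species", "timestamp"])
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    return frame
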
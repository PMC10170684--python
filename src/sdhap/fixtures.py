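"""Packaged locus fixtures.

``load_grch38_model`` builds the 3q29 locus model on GRCh38 coordinates from
the packaged BED/YAML (a synthetic reconstruction of the published layout:
copy counts, block membership and cassette positions are faithful, exact
coordinates are approximate).  ``reference_cohort_calls`` reconstructs a
per-chromosome haplotype-call table from the published headline tallies of
the 161-individual unaffected cohort; it is a synthetic stand-in for the
deposited supplementary call table and is used to exercise cohort
summarisation arithmetic.
"""

from __future__ import annotations

import warnings
from importlib import resources

import pandas as pd

from . import io as sdio
from .locus import ReferenceLocusModel, build_reference_model


def _data_path(name: str):
    return resources.files("sdhap.data") / name


def load_grch38_model() -> ReferenceLocusModel:
    """The packaged 3q29 model (coordinates only; no sequences)."""
    cfg_raw = sdio.read_locus_config(_data_path("grch38_3q29_locus.yaml"))
    import yaml

    with open(_data_path("grch38_3q29_locus.yaml")) as fh:
        raw = yaml.safe_load(fh)
    entries = sdio.read_bed(_data_path("grch38_3q29_segments.bed"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = build_reference_model(
            entries,
            critical_regions=cfg_raw["critical_regions"],
            region=cfg_raw["region"],
            canonical_lengths=raw.get("segment_lengths"),
            parent_segments=raw.get("parent_segments"),
        )
    return model


# headline tallies of the unaffected cohort: 322 chromosomes, 33 haplotypes,
# top three H3/H1/H2, 14 singletons
_COHORT_COUNTS = {
    "H3": 48, "H1": 46, "H2": 40, "H5": 30, "H4": 20, "H6": 18, "H7": 16,
    "H8": 12, "H9": 10, "H13": 10, "H15": 10, "H16": 10, "H17": 8, "H18": 8,
    "H19": 6, "H20": 6, "H21": 4, "H22": 3, "H23": 3,
    **{f"H{i}": 1 for i in range(24, 37)}, "INV-1": 1,
}

_POP_CYCLE = ["AFR", "AMR", "EAS", "EUR", "SAS"]


def reference_cohort_calls() -> pd.DataFrame:
    """Synthetic reconstruction of the cohort's per-chromosome calls.

    Counts reproduce the published headline frequencies (H3 48/322, H1
    46/322, H2 40/322, 14 singletons among 33 haplotypes); population
    labels are cycled and carry no information.
    """
    rows = []
    i = 0
    for hap, n in _COHORT_COUNTS.items():
        for _ in range(n):
            rows.append({"chromosome": f"chr_{i:03d}",
                         "haplotype_id": hap,
                         "population": _POP_CYCLE[i % 5]})
            i += 1
    assert i == 322
    return pd.DataFrame(rows)
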
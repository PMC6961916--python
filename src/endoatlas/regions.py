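"""Fixed region vocabulary shared across the package.

The analysis compares three whole-brain regions — hippocampus (HPC),
cortex (CX), cerebellum (CB) — and four hippocampal subfields — the
cornu ammonis fields CA1, CA2, CA3 and the dentate gyrus (DG).
"""

from __future__ import annotations

#: Whole-brain regions compared against each other.
BRAIN_REGIONS: tuple[str, ...] = ("HPC", "CX", "CB")

#: Hippocampal subfields; DG is contrasted with the mean of the CA fields.
SUBFIELDS: tuple[str, ...] = ("CA1", "CA2", "CA3", "DG")

CA_FIELDS: tuple[str, ...] = ("CA1", "CA2", "CA3")

#: All region columns in the intensity-table dialect, in canonical order.
ALL_REGIONS: tuple[str, ...] = BRAIN_REGIONS + SUBFIELDS

#: Integer labels used in paletted mask images. 0 is background.
MASK_LABELS: dict[str, int] = {
    "background": 0,
    "HPC:CA1": 1,
    "HPC:CA2": 2,
    "HPC:CA3": 3,
    "HPC:DG": 4,
    "CX": 5,
    "CB": 6,
}

#: Mask labels whose union constitutes the whole hippocampus.
HPC_MASK_LABELS: tuple[str, ...] = ("HPC:CA1", "HPC:CA2", "HPC:CA3", "HPC:DG")

#: Mask label carrying each subfield.
SUBFIELD_MASK: dict[str, str] = {
    "CA1": "HPC:CA1",
    "CA2": "HPC:CA2",
    "CA3": "HPC:CA3",
    "DG": "HPC:DG",
}


class EndoatlasError(Exception):
    """Base class for package errors."""


class ConfigurationError(EndoatlasError):
    """Invalid configuration value (fold, proportion, replicate count...)."""


class SchemaError(EndoatlasError):
    """Malformed input table (missing column, duplicate gene, bad value)."""


class GeometryError(EndoatlasError):
    """ROI outside image bounds, empty ROI, or region missing from a mask."""


class UndefinedTestError(EndoatlasError):
    """A statistic is undefined on the given data (e.g. zero variance)."""
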
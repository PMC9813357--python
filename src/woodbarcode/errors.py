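"""Exception hierarchy.

Each error class maps to a distinct CLI exit code (see ``cli.py``) so that
callers scripting the pipeline can distinguish bad inputs from analysis
failures such as saturated distances.
"""


class WoodBarcodeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class AlignmentError(WoodBarcodeError):
    """Malformed alignment: ragged rows, duplicate ids, illegal residues."""

    exit_code = 3


class SampleTableError(WoodBarcodeError):
    """Malformed or inconsistent sample metadata."""

    exit_code = 3


class NewickError(WoodBarcodeError):
    """Unparseable Newick input."""

    exit_code = 3


class UndefinedDistanceError(WoodBarcodeError):
    """A pairwise distance is undefined (saturated or insufficient overlap)
    in a context that requires a complete matrix."""

    exit_code = 4


class BootstrapError(WoodBarcodeError):
    """Too many bootstrap replicates were unusable."""

    exit_code = 4


class IdentificationError(WoodBarcodeError):
    """A query cannot be placed (e.g. shares no locus with the library)."""

    exit_code = 5
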
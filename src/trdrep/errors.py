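"""Exception hierarchy for the TRD repertoire pipeline."""


class TrdrepError(Exception):
    """Base class for all pipeline errors."""


class GermlineFormatError(TrdrepError):
    """Malformed germline input (duplicate ids, bad alphabet, missing records)."""


class AnchorError(GermlineFormatError):
    """A V/J anchor is missing, out of range, or its codon is not C (V) / F or W (J)."""


class PrimerSiteError(TrdrepError):
    """A declared primer does not bind exactly once at its declared site."""


class SimulationError(TrdrepError):
    """Rearrangement simulation failed (e.g. repeated trimming exhaustion)."""


class ParameterError(TrdrepError):
    """Invalid simulation or analysis parameters."""


class AnnotationError(TrdrepError):
    """CDR3 extraction / translation failure on a read."""


class FrameError(AnnotationError):
    """Nucleotide length not divisible by three."""


class EmptyTableError(TrdrepError):
    """An operation requiring at least one usable record received none."""


class TieError(TrdrepError):
    """An operation requiring a unique winner found a tie the caller must resolve."""


class InputFormatError(TrdrepError):
    """Malformed tabular input; message carries the offending line/row."""


class DegenerateDataError(TrdrepError):
    """Statistics undefined on the given data (all-zero differences, zero variance...)."""
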
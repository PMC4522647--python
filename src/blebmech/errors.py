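"""Exception hierarchy for the blebmech package.

Analysis routines raise these instead of bare ValueErrors so batch drivers
can convert failures into per-item rejection records rather than aborting.
"""


class BlebmechError(Exception):
    """Base class for all blebmech errors."""


# --- AFM mechanics ---------------------------------------------------------

class NoContact(BlebmechError):
    """Deflection never persistently exceeds the baseline noise threshold."""


class DegenerateBaseline(NoContact):
    """Baseline noise SD is zero and the deflection never rises (a flat,
    noiseless trace is the degenerate case of no contact)."""


class RigidContact(BlebmechError):
    """Deflection slope >= 1: deflection tracks the piezo, the soft-contact
    force-balance model is invalid (infinitely stiff sample)."""


class InsufficientPoints(BlebmechError):
    """Fewer than the minimum number of samples inside the fit window."""


# --- Morphometry -----------------------------------------------------------

class EmptyRegion(BlebmechError):
    """A line, ROI or mask covers zero pixels."""


class NoPeak(BlebmechError):
    """An intensity profile is monotone over the window; no interior peak."""


class NoBleb(BlebmechError):
    """No lobe beyond the cell body could be separated from the mask."""


class EmptyBin(BlebmechError):
    """A regional bin along the bleb axis captured zero pixels."""


class ZeroGradient(BlebmechError):
    """No pixel in the ROI has a nonzero intensity gradient."""


class ZeroMean(BlebmechError):
    """ROI mean intensity is zero; contrast index undefined."""


class NeverAboveBackground(BlebmechError):
    """Rim intensity never exceeds the background level; arrival undefined."""


# --- Ratiometric imaging ---------------------------------------------------

class EmptyROI(BlebmechError):
    """Background ROI contains no pixels."""


class FitFailure(BlebmechError):
    """A nonlinear fit did not converge."""


class EmptyMask(BlebmechError):
    """Thresholding removed every pixel."""


class NoSignal(BlebmechError):
    """Total photoconverted signal is ~0 after the conversion frame."""


# --- Pipeline --------------------------------------------------------------

class ConfigInvalid(BlebmechError):
    """Pipeline configuration fails schema validation."""


class InputMissing(BlebmechError):
    """A referenced input path does not exist."""


class StageFailure(BlebmechError):
    """A pipeline stage failed; carries the stage name and reason."""

    def __init__(self, stage: str, reason: str):
        self.stage = stage
        self.reason = reason
        super().__init__(f"stage '{stage}' failed: {reason}")


class UnknownColumn(BlebmechError):
    """A requested grouping or value column is absent from the table."""
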
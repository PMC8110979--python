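"""Exception and warning types shared across the package."""


class AirwayMorphError(Exception):
    """Base class for all package-specific errors."""


class CollinearPointsError(AirwayMorphError):
    """Three points are collinear (triangle area below tolerance)."""


class DegenerateAverageError(AirwayMorphError):
    """Sign-aligned normals average to a near-zero vector."""


class MissingLandmarkError(AirwayMorphError, KeyError):
    """A required landmark is absent from the landmark set."""

    def __init__(self, names):
        if isinstance(names, str):
            names = [names]
        self.names = list(names)
        super().__init__(f"missing landmark(s): {', '.join(self.names)}")


class DegenerateFrameError(AirwayMorphError):
    """Reference-frame construction is ill-conditioned (e.g. the
    nasion-opisthion axis is parallel to the Frankfort normal)."""


class DegenerateAngleError(AirwayMorphError):
    """An angle ray has near-zero length."""


class OpenMeshError(AirwayMorphError):
    """Mesh is not closed/watertight; region quantities are undefined."""


class InvalidRegionError(AirwayMorphError):
    """Region bounding planes are not parallel or are inverted (the lower
    plane does not lie strictly below the upper one)."""


class EmptyRegionWarning(UserWarning):
    """The slab between the bounding planes misses the mesh entirely."""


class NonPositiveDataError(AirwayMorphError):
    """Log-scale growth fitting requires strictly positive ages/values."""


class NonPositiveAgeError(AirwayMorphError):
    """Prediction requested at a non-positive age."""


class InsufficientDataError(AirwayMorphError):
    """Too few observations for the requested statistic."""


class MissingFitError(AirwayMorphError, KeyError):
    """No control growth fit available for a requested measurement."""


class SeparationError(AirwayMorphError):
    """Perfect separation: the logistic MLE does not exist."""


class NoVarianceError(AirwayMorphError):
    """Outcome or a predictor is constant."""


class NonConvergenceError(AirwayMorphError):
    """Iterative fit failed to converge."""


class SingleClassError(AirwayMorphError):
    """ROC analysis requires both label classes."""


class ConfigError(AirwayMorphError):
    """Invalid configuration (unknown keys, inconsistent values)."""
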
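"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """A configuration object violates its invariants."""


class GeometryError(ValueError):
    """Grids or geometric primitives are inconsistent (shape/spacing mismatch,
    bone outside the body contour, ROI out of bounds, ...)."""


class SeedError(ValueError):
    """A region-growing seed does not satisfy the growth predicate."""


class InputError(ValueError):
    """Voxel data fed to an operation is invalid (non-finite HU, unknown
    tissue label, negative attenuation coefficient, ...)."""
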
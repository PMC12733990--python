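class SizingError(ValueError):
    """A volume, cohort or lesion size request that cannot be honoured."""


class ConfigurationError(ValueError):
    """Inconsistent network or pipeline configuration."""


class MetadataError(ValueError):
    """Missing or invalid volume metadata (e.g. non-positive voxel spacing)."""
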
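"""Package exception hierarchy."""


class NucshellError(Exception):
    """Base class for all nucshell errors."""


class SizingError(NucshellError):
    """A simulated object does not fit the voxel grid."""


class DegenerateGeometryError(NucshellError):
    """A voxel set is too thin/empty for the requested geometric operation."""
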
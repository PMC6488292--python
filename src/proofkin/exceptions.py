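"""Package-level exception types."""


class FitConvergenceError(RuntimeError):
    """A nonlinear least-squares fit failed to converge or was degenerate."""
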
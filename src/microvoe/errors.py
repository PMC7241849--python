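"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """Raised when a study design, signal spec or run config is invalid."""


class EvaluationFailure(RuntimeError):
    """Raised when a model evaluation fails (memory, convergence, degenerate fold).

    The hyperparameter tuner catches this and shrinks the explorable range of
    the offending hyperparameter instead of aborting the search.
    """
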
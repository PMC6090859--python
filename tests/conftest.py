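import hypothesis

hypothesis.settings.register_profile(
    "det", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("det")
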
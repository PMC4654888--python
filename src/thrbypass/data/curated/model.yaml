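atp_per_nadh: 56/33
cofactor_policy: merged
name: curated threonine-bypass core network
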
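ef617042ba7a0488aa8647594789ad00d042ca5f1030433b6580c365b66b89d0
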
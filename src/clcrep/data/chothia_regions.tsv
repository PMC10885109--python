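region	start	end
FR-L1	1	23
CDR-L1	24	34
FR-L2	35	49
CDR-L2	50	56
FR-L3	57	88
CDR-L3	89	97
FR-L4	98	107
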
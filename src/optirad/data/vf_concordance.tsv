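patient	overlap_present	preop_vf	postop_vf
Patient04	True	normal	abnormal
Patient09	False	normal	normal
Patient13	True	normal	abnormal
Patient15	True	normal	abnormal
Patient17	False	normal	normal
Patient18	True	normal	abnormal
Patient25	False	normal	normal
Patient31	False	normal	normal
Patient32	False	normal	normal
Patient39	True	normal	abnormal
Patient42	True	normal	abnormal
Patient43	True	normal	abnormal
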
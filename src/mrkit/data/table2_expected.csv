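outcome,method,pval,or,or_lci95,or_uci95
Lymphomas,MR-Egger,9.70e-1,1.00,1.00,1.00
Lymphomas,Weighted median,9.68e-1,1.00,1.00,1.00
Lymphomas,Inverse variance weighted,6.12e-1,1.00,1.00,1.00
Lymphomas,MR-PRESSO,5.86e-1,1.00,1.00,1.00
Diffuse large B-cell lymphoma,MR-Egger,5.34e-1,0.68,0.21,2.21
Diffuse large B-cell lymphoma,Weighted median,3.45e-1,0.82,0.54,1.24
Diffuse large B-cell lymphoma,Inverse variance weighted,3.34e-1,0.85,0.62,1.18
Diffuse large B-cell lymphoma,MR-PRESSO,3.06e-1,0.85,0.64,1.14
Follicular lymphoma,MR-Egger,3.52e-1,0.69,0.32,1.46
Follicular lymphoma,Weighted median,1.42e-1,0.81,0.62,1.07
Follicular lymphoma,Inverse variance weighted,6.49e-1,0.95,0.78,1.17
Follicular lymphoma,MR-PRESSO,5.93e-1,0.95,0.80,1.13
Hodgkin lymphoma,MR-Egger,5.82e-1,0.77,0.31,1.89
Hodgkin lymphoma,Weighted median,7.15e-1,1.06,0.77,1.46
Hodgkin lymphoma,Inverse variance weighted,4.66e-1,1.10,0.86,1.40
Hodgkin lymphoma,MR-PRESSO,4.55e-1,1.10,0.87,1.38
Non-follicular lymphoma,MR-Egger,8.30e-1,0.94,0.52,1.69
Non-follicular lymphoma,Weighted median,9.70e-1,1.00,0.82,1.20
Non-follicular lymphoma,Inverse variance weighted,5.80e-1,0.96,0.82,1.12
Non-follicular lymphoma,MR-PRESSO,5.92e-1,0.96,0.82,1.12
Other and unspecified types of non-Hodgkin lymphoma,MR-Egger,6.02e-1,0.81,0.39,1.71
Other and unspecified types of non-Hodgkin lymphoma,Weighted median,9.87e-1,1.00,0.77,1.30
Other and unspecified types of non-Hodgkin lymphoma,Inverse variance weighted,8.39e-1,0.98,0.80,1.20
Other and unspecified types of non-Hodgkin lymphoma,MR-PRESSO,7.36e-1,0.98,0.87,1.10
Mature T/NK-cell lymphomas,MR-Egger,1.91e-1,0.36,0.09,1.48
Mature T/NK-cell lymphomas,Weighted median,4.12e-2,1.74,1.02,2.97
Mature T/NK-cell lymphomas,Inverse variance weighted,5.32e-3,1.72,1.18,2.53
Mature T/NK-cell lymphomas,MR-PRESSO,1.79e-2,1.72,1.18,2.52
Small intestine/small bowel cancer,MR-Egger,1.21e-1,1.00,1.00,1.00
Small intestine/small bowel cancer,Weighted median,6.46e-1,1.00,1.00,1.00
Small intestine/small bowel cancer,Inverse variance weighted,8.35e-1,1.00,1.00,1.00
Small intestine/small bowel cancer,MR-PRESSO,8.39e-1,1.00,1.00,1.00
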
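image_id,label,x_min,y_min,x_max,y_max,source_id,blob_count,tunnel,hollow
phantom_0000,N,22,19,58,61,phantom_N_0000,1,False,False
phantom_0000,E,90,25,136,55,phantom_E_0000,0,False,True
phantom_0000,E,168,22,204,58,phantom_E_0001,0,False,True
phantom_0000,N,238,25,280,55,phantom_N_0001,1,False,False
phantom_0000,M,23,91,58,136,phantom_M_0000,2,False,False
phantom_0000,M,92,93,135,134,phantom_M_0001,2,False,False
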
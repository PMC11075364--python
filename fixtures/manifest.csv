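image_id,image_path,voc_path,yolo_path,width,height,n_boxes,n_M,n_N,n_E
phantom_0000,images/phantom_0000.png,annotations/voc/phantom_0000.xml,annotations/yolo/phantom_0000.txt,360,360,6,2,2,2
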
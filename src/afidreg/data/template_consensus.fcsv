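# Markups fiducial file version = 4.11
# CoordinateSystem = RAS
# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID
vtkMRMLMarkupsFiducialNode_1,-0.24,1.88,-4.75,0,0,0,1,1,1,0,AC,anterior commissure,
vtkMRMLMarkupsFiducialNode_2,-0.06,-24.68,-2.36,0,0,0,1,1,1,0,PC,posterior commissure,
vtkMRMLMarkupsFiducialNode_3,-0.10,-33.10,-14.20,0,0,0,1,1,1,0,ICS,infracollicular sulcus (approximate),
vtkMRMLMarkupsFiducialNode_4,0.00,-36.50,-31.00,0,0,0,1,1,1,0,PMJ,pontomedullary junction (approximate),
vtkMRMLMarkupsFiducialNode_5,-0.20,-14.30,-12.20,0,0,0,1,1,1,0,SIPF,superior interpeduncular fossa (approximate),
vtkMRMLMarkupsFiducialNode_6,8.50,-18.50,-12.00,0,0,0,1,1,1,0,RSLMS,right superior lateral mesencephalic sulcus (approximate),
vtkMRMLMarkupsFiducialNode_7,-8.50,-18.50,-12.00,0,0,0,1,1,1,0,LSLMS,left superior lateral mesencephalic sulcus (approximate),
vtkMRMLMarkupsFiducialNode_8,10.00,-24.00,-20.00,0,0,0,1,1,1,0,RILMS,right inferior lateral mesencephalic sulcus (approximate),
vtkMRMLMarkupsFiducialNode_9,-10.00,-24.00,-20.00,0,0,0,1,1,1,0,LILMS,left inferior lateral mesencephalic sulcus (approximate),
vtkMRMLMarkupsFiducialNode_10,0.00,-52.00,3.00,0,0,0,1,1,1,0,CUL,culmen (approximate),
vtkMRMLMarkupsFiducialNode_11,0.00,-9.20,-16.00,0,0,0,1,1,1,0,IMS,intermammillary sulcus (approximate),
vtkMRMLMarkupsFiducialNode_12,2.60,-9.00,-15.80,0,0,0,1,1,1,0,RMB,right mammillary body (approximate),
vtkMRMLMarkupsFiducialNode_13,-2.60,-9.00,-15.80,0,0,0,1,1,1,0,LMB,left mammillary body (approximate),
vtkMRMLMarkupsFiducialNode_14,0.00,-28.80,1.50,0,0,0,1,1,1,0,PG,pineal gland (approximate),
vtkMRMLMarkupsFiducialNode_15,14.50,3.00,15.00,0,0,0,1,1,1,0,RLVAC,right lateral aspect of frontal horn at AC (approximate),
vtkMRMLMarkupsFiducialNode_16,-14.50,3.00,15.00,0,0,0,1,1,1,0,LLVAC,left lateral aspect of frontal horn at AC (approximate),
vtkMRMLMarkupsFiducialNode_17,17.00,-26.00,18.00,0,0,0,1,1,1,0,RLVPC,right lateral aspect of frontal horn at PC (approximate),
vtkMRMLMarkupsFiducialNode_18,-17.00,-26.00,18.00,0,0,0,1,1,1,0,LLVPC,left lateral aspect of frontal horn at PC (approximate),
vtkMRMLMarkupsFiducialNode_19,0.00,27.00,8.00,0,0,0,1,1,1,0,GENU,genu of corpus callosum (approximate),
vtkMRMLMarkupsFiducialNode_20,0.00,-37.50,12.00,0,0,0,1,1,1,0,SPL,splenium of corpus callosum (approximate),
vtkMRMLMarkupsFiducialNode_21,33.00,-6.00,-20.00,0,0,0,1,1,1,0,RALTH,right anterolateral temporal horn (approximate),
vtkMRMLMarkupsFiducialNode_22,-33.00,-6.00,-20.00,0,0,0,1,1,1,0,LALTH,left anterolateral temporal horn (approximate),
vtkMRMLMarkupsFiducialNode_23,31.00,-10.00,-14.00,0,0,0,1,1,1,0,RSAMTH,right superior anteromedial temporal horn (approximate),
vtkMRMLMarkupsFiducialNode_24,-31.00,-10.00,-14.00,0,0,0,1,1,1,0,LSAMTH,left superior anteromedial temporal horn (approximate),
vtkMRMLMarkupsFiducialNode_25,30.00,-8.00,-21.00,0,0,0,1,1,1,0,RIAMTH,right inferior anteromedial temporal horn (approximate),
vtkMRMLMarkupsFiducialNode_26,-30.00,-8.00,-21.00,0,0,0,1,1,1,0,LIAMTH,left inferior anteromedial temporal horn (approximate),
vtkMRMLMarkupsFiducialNode_27,3.00,-38.00,15.00,0,0,0,1,1,1,0,RIGO,right indusium griseum origin (approximate),
vtkMRMLMarkupsFiducialNode_28,-3.00,-38.00,15.00,0,0,0,1,1,1,0,LIGO,left indusium griseum origin (approximate),
vtkMRMLMarkupsFiducialNode_29,21.00,-78.00,3.00,0,0,0,1,1,1,0,RVOH,right ventral occipital horn (approximate),
vtkMRMLMarkupsFiducialNode_30,-21.00,-78.00,3.00,0,0,0,1,1,1,0,LVOH,left ventral occipital horn (approximate),
vtkMRMLMarkupsFiducialNode_31,7.00,30.00,-22.00,0,0,0,1,1,1,0,ROSF,right olfactory sulcal fundus (approximate),
vtkMRMLMarkupsFiducialNode_32,-7.00,30.00,-22.00,0,0,0,1,1,1,0,LOSF,left olfactory sulcal fundus (approximate)
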